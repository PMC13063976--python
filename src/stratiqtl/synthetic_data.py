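"""Synthetic three-breed genotype, expression and GWAS data.

The generator emulates the statistical structure a breed-stratified
cis-eQTL study assumes: three diverged populations of equal size,
allele-frequency divergence following the Balding–Nichols model, local
LD from first-order haplotype correlation, expression traits with a
planted cis effect, a GRM-structured polygenic background and
independent noise, and single-trait GWAS summary statistics whose
signals may or may not share the eQTL causal variant.

Everything is reproducible from ``SimConfig.seed``; identical configs
give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BREEDS, ExpressionMatrix, GenotypeMatrix, GwasSummary

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthTable",
    "ConfigError",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_gwas",
    "simulate_study",
]

#: cis window half-width (bp) used to place causal variants, matching the
#: mapping window of +/- 1 Mb around the TSS.
CIS_WINDOW = 1_000_000


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the three-breed synthetic study.

    Defaults mirror the design being emulated: 100 individuals in each of
    three breeds, moderate breed divergence, a cis effect explaining 30%
    of expression variance where planted, and a polygenic background.
    """

    n_per_breed: int = 100
    n_variants: int = 2000
    n_genes: int = 100
    chrom_length: int = 100_000_000
    fst: float = 0.1
    ld_rho: float = 0.6
    frac_shared_egenes: float = 0.35
    frac_specific_egenes: float = 0.15
    cis_h2: float = 0.3
    polygenic_h2: float = 0.2
    gwas_n: int = 10_000
    gwas_frac_coloc: float = 0.5
    gwas_var_explained: float = 0.005
    #: among shared eGenes, fraction planted in all three breeds (the rest
    #: are planted in a random pair)
    shared3_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst < 1.0):
            raise ConfigError(f"fst must be in (0, 1), got {self.fst}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        for name in (
            "frac_shared_egenes",
            "frac_specific_egenes",
            "cis_h2",
            "polygenic_h2",
            "gwas_frac_coloc",
            "shared3_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_shared_egenes + self.frac_specific_egenes > 1.0 + 1e-12:
            raise ConfigError("frac_shared_egenes + frac_specific_egenes > 1")
        if self.cis_h2 + self.polygenic_h2 >= 1.0:
            raise ConfigError("cis_h2 + polygenic_h2 must be < 1")
        for name in ("n_per_breed", "n_variants", "n_genes", "chrom_length", "gwas_n"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class TruthTable:
    """Planted ground truth for recovery tests.

    One row per gene: ``gene_id``, ``category`` (``shared3``,
    ``shared2:<B1>+<B2>``, ``specific:<B>`` or ``null``), the shared
    ``causal_variant`` id (empty for null genes) and one ``true_beta_<breed>``
    column per breed (NaN where the breed carries no effect).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        beta_cols = [f"true_beta_{b}" for b in BREEDS]
        for _, row in self.table.iterrows():
            active = [b for b in BREEDS if np.isfinite(row[f"true_beta_{b}"])]
            cat = row["category"]
            if cat == "null" and active:
                raise ValueError(f"null gene {row['gene_id']} has active betas")
            if cat == "shared3":
                if len(active) != 3:
                    raise ValueError(f"shared3 gene {row['gene_id']} has {active}")
                signs = {np.sign(row[f"true_beta_{b}"]) for b in active}
                if len(signs) != 1:
                    raise ValueError(f"shared3 gene {row['gene_id']} sign-discordant")
            if cat.startswith("shared2") and len(active) != 2:
                raise ValueError(f"shared2 gene {row['gene_id']} has {active}")
            if cat.startswith("specific") and len(active) != 1:
                raise ValueError(f"specific gene {row['gene_id']} has {active}")
        self._beta_cols = beta_cols

    def active_breeds(self, gene_id: str) -> list[str]:
        row = self.table.set_index("gene_id").loc[gene_id]
        return [b for b in BREEDS if np.isfinite(row[f"true_beta_{b}"])]

    @property
    def egene_mask(self) -> np.ndarray:
        return (self.table["category"] != "null").to_numpy()


def _balding_nichols_freqs(
    p_anc: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-breed allele frequencies under the Balding–Nichols model."""
    scale = (1.0 - fst) / fst
    a = p_anc * scale
    b = (1.0 - p_anc) * scale
    freqs = rng.beta(a, b, size=(len(BREEDS), len(p_anc)))
    # avoid exactly monomorphic breeds; downstream QC handles near-fixed sites
    return np.clip(freqs, 1e-3, 1.0 - 1e-3)


def _ar1_haplotypes(
    freqs: np.ndarray, n_hap: int, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Haplotypes with first-order latent-Gaussian correlation ``rho``.

    A latent AR(1) Gaussian per haplotype is thresholded at the normal
    quantile of each variant's frequency, preserving marginal frequencies
    while inducing monotone-in-rho correlation between adjacent variants.
    """
    m = freqs.shape[0]
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        eps = rng.standard_normal((n_hap, m - 1))
        c = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + c * eps[:, j - 1]
    thresh = stats.norm.ppf(freqs)
    return (z < thresh[None, :]).astype(np.int8)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate dosages for 3 x ``n_per_breed`` samples on one chromosome.

    Ancestral frequencies are uniform on [0.05, 0.95]; each breed's
    frequency is Beta-distributed around the ancestral value with variance
    ``fst * p * (1 - p)`` (Balding–Nichols); haplotypes carry first-order
    adjacent-variant correlation ``ld_rho``; positions are evenly spaced.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    p_anc = rng.uniform(0.05, 0.95, size=m)
    breed_freqs = _balding_nichols_freqs(p_anc, config.fst, rng)

    blocks = []
    sample_rows = []
    for bi, breed in enumerate(BREEDS):
        n = config.n_per_breed
        h1 = _ar1_haplotypes(breed_freqs[bi], n, config.ld_rho, rng)
        h2 = _ar1_haplotypes(breed_freqs[bi], n, config.ld_rho, rng)
        blocks.append(h1 + h2)
        sample_rows.extend(
            {"id": f"{breed[0]}{i:03d}", "breed": breed} for i in range(n)
        )
    dosage = np.vstack(blocks).astype(np.int8)

    spacing = max(1, config.chrom_length // (m + 1))
    pos = spacing * np.arange(1, m + 1)
    variants = pd.DataFrame(
        {
            "id": [f"snp{j}" for j in range(m)],
            "chrom": "1",
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    gm = GenotypeMatrix(dosage, variants, pd.DataFrame(sample_rows))
    gm.ancestral_freq = p_anc  # exposed for calibration checks
    gm.breed_freqs = breed_freqs
    return gm


def _assign_categories(config: SimConfig, rng: np.random.Generator) -> list[str]:
    n = config.n_genes
    n_shared = int(round(config.frac_shared_egenes * n))
    n_specific = int(round(config.frac_specific_egenes * n))
    n_shared3 = int(round(config.shared3_fraction * n_shared))
    cats: list[str] = []
    for _ in range(n_shared3):
        cats.append("shared3")
    for _ in range(n_shared - n_shared3):
        i, j = sorted(rng.choice(3, size=2, replace=False))
        cats.append(f"shared2:{BREEDS[i]}+{BREEDS[j]}")
    for _ in range(n_specific):
        cats.append(f"specific:{BREEDS[rng.integers(3)]}")
    cats.extend("null" for _ in range(n - len(cats)))
    rng.shuffle(cats)
    return cats


def _category_breeds(category: str) -> list[str]:
    if category == "shared3":
        return list(BREEDS)
    if category.startswith("shared2:"):
        return category.split(":")[1].split("+")
    if category.startswith("specific:"):
        return [category.split(":")[1]]
    return []


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[ExpressionMatrix, TruthTable]:
    """Plant cis effects and a polygenic background; emit read counts.

    For each gene the latent trait is ``beta * centered causal dosage``
    (scaled so its within-breed variance share is ``cis_h2``; absent for
    null genes/breeds) plus a multivariate polygenic draw with covariance
    ``polygenic_h2 * GRM`` of the breed, plus Gaussian noise topping the
    variance up to 1.  Counts are Poisson around
    ``library_factor * baseline * exp(latent)`` — a monotone positive link;
    only its monotonicity is relied on downstream.
    """
    from .eqtl_lmm import compute_grm  # local import avoids a cycle at import time

    if config.n_genes < 1 or genotypes.n_variants < 1:
        raise ConfigError("need at least one gene and one variant")
    rng = np.random.default_rng(config.seed + 1)
    n_total = genotypes.n_samples
    pos = genotypes.variants["pos"].to_numpy()
    # candidate causal variants must be common within every breed so the
    # planted effect is observable in each active breed and the variant
    # survives the cross-breed QC intersection
    breed_maf = np.column_stack(
        [
            np.minimum(f, 1 - f)
            for f in (
                genotypes.dosage[genotypes.breed_mask(b), :].mean(axis=0) / 2.0
                for b in BREEDS
            )
        ]
    )
    min_breed_maf = breed_maf.min(axis=1)

    # evenly spaced gene TSSs over the simulated chromosome
    span = int(pos[-1])
    tss = np.linspace(span * 0.05, span * 0.95, config.n_genes).astype(int) + 1
    genes = pd.DataFrame(
        {
            "id": [f"gene{g}" for g in range(config.n_genes)],
            "chrom": "1",
            "tss": tss,
            "strand": np.where(np.arange(config.n_genes) % 2 == 0, "+", "-"),
            "length": rng.integers(5_000, 50_000, size=config.n_genes),
        }
    )

    categories = _assign_categories(config, rng)

    # polygenic background per breed, from that breed's realized GRM
    breed_masks = {b: genotypes.breed_mask(b) for b in BREEDS}
    chol = {}
    for b in BREEDS:
        sub = genotypes.for_breed(b)
        poly = sub.dosage.std(axis=0) > 0  # breed-monomorphic sites carry no signal
        grm = compute_grm(sub.subset(variant_mask=poly)).values
        w, v = np.linalg.eigh(grm)
        chol[b] = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    latent = np.zeros((config.n_genes, n_total))
    truth_rows = []
    sigma_noise_base = np.sqrt(1.0 - config.polygenic_h2)
    sigma_noise_cis = np.sqrt(max(1.0 - config.cis_h2 - config.polygenic_h2, 0.0))

    for gi in range(config.n_genes):
        cat = categories[gi]
        active = _category_breeds(cat)
        causal_id = ""
        betas = {b: np.nan for b in BREEDS}
        causal_idx = -1
        if active:
            in_cis = np.flatnonzero(
                (pos >= tss[gi] - CIS_WINDOW)
                & (pos <= tss[gi] + CIS_WINDOW)
                & (min_breed_maf >= 0.05)
            )
            if in_cis.size == 0:
                in_cis = np.array([int(np.argmin(np.abs(pos - tss[gi])))])
            causal_idx = int(rng.choice(in_cis))
            causal_id = genotypes.variants["id"].iloc[causal_idx]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        for b in BREEDS:
            mask = breed_masks[b]
            nb = mask.sum()
            g_poly = (
                chol[b] @ rng.standard_normal(nb)
            ) * np.sqrt(config.polygenic_h2)
            if b in active and config.cis_h2 > 0:
                s = genotypes.dosage[mask, causal_idx].astype(float)
                s -= s.mean()
                v_s = s.var()
                if v_s <= 0:  # monomorphic in this breed: effect unobservable
                    beta_b = 0.0
                    cis_part = 0.0
                    noise = sigma_noise_base
                else:
                    beta_b = sign * np.sqrt(config.cis_h2 / v_s)
                    cis_part = beta_b * s
                    noise = sigma_noise_cis
                betas[b] = beta_b
                latent[gi, mask] = (
                    cis_part + g_poly + noise * rng.standard_normal(nb)
                )
            else:
                if b in active:  # cis_h2 == 0 configuration
                    betas[b] = 0.0
                latent[gi, mask] = g_poly + sigma_noise_base * rng.standard_normal(nb)
        truth_rows.append(
            {
                "gene_id": genes["id"].iloc[gi],
                "tss": int(tss[gi]),
                "category": cat,
                "causal_variant": causal_id,
                **{f"true_beta_{b}": betas[b] for b in BREEDS},
            }
        )

    baseline = rng.lognormal(mean=np.log(200.0), sigma=1.0, size=config.n_genes)
    lib_factor = rng.lognormal(mean=0.0, sigma=0.2, size=n_total)
    mu = lib_factor[None, :] * baseline[:, None] * np.exp(latent)
    counts = rng.poisson(mu).astype(float)

    expr = ExpressionMatrix(
        counts, "counts", genes, list(genotypes.samples["id"])
    )
    expr.latent = latent  # exposed for variance-share calibration checks
    return expr, TruthTable(pd.DataFrame(truth_rows))


def _marginal_z_means(
    genotypes: GenotypeMatrix,
    causal_idx: np.ndarray,
    causal_z: np.ndarray,
    window: int = 2_000_000,
) -> np.ndarray:
    """Expected marginal z-scores via pooled genotype correlations.

    A variant's expected marginal z is the sum over causal variants of
    ``r * z_causal`` with ``r`` the pooled dosage correlation; variants
    beyond ``window`` of every causal site have mean 0.
    """
    pos = genotypes.variants["pos"].to_numpy()
    d = genotypes.dosage.astype(float)
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = np.inf
    z_mean = np.zeros(genotypes.n_variants)
    n = genotypes.n_samples
    for c, zc in zip(causal_idx, causal_z):
        near = np.flatnonzero(np.abs(pos - pos[c]) <= window)
        r = (d[:, near].T @ d[:, c]) / (n * sd[near] * sd[c])
        z_mean[near] += r * zc
    return z_mean


def simulate_gwas(
    genotypes: GenotypeMatrix,
    truth: TruthTable,
    config: SimConfig,
    trait: str = "trait",
    causal_variants: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> GwasSummary:
    """Single-trait GWAS summary statistics with planted signals.

    By default, every planted eGene contributes one trait signal: for a
    ``gwas_frac_coloc`` fraction the trait's causal variant is the eQTL
    causal variant itself; for the rest it is a nearby variant in low LD
    (pooled r^2 < 0.2) when one exists.  Passing ``causal_variants``
    overrides this (an empty list gives a pure-null trait).  Effect sizes
    give each causal variant ``gwas_var_explained`` of trait variance;
    ``se^2 = 1 / (2 n p (1-p))`` and ``beta_hat ~ N(beta, se^2)``.
    """
    if config.gwas_n <= 0:
        raise ConfigError("gwas_n must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    vid_to_idx = {v: i for i, v in enumerate(genotypes.variants["id"])}
    pooled = genotypes.dosage.astype(float)
    p = pooled.mean(axis=0) / 2.0
    het = 2.0 * p * (1.0 - p)
    with np.errstate(divide="ignore"):
        se = np.where(het > 0, 1.0 / np.sqrt(config.gwas_n * het), np.inf)

    planted_rows = []
    if causal_variants is None:
        causal_idx = []
        egenes = truth.table.loc[truth.egene_mask]
        n_coloc = int(round(config.gwas_frac_coloc * len(egenes)))
        order = rng.permutation(len(egenes))
        for rank, row_i in enumerate(order):
            row = egenes.iloc[row_i]
            eqtl_idx = vid_to_idx[row["causal_variant"]]
            if rank < n_coloc:
                cidx, shared = eqtl_idx, True
            else:
                # the distinct causal variant stays inside the gene's cis
                # window so its signal is visible to colocalization
                center = int(row["tss"]) if "tss" in row else None
                cidx = _low_ld_neighbor(genotypes, eqtl_idx, rng, center_pos=center)
                shared = False
            causal_idx.append(cidx)
            planted_rows.append(
                {
                    "gene_id": row["gene_id"],
                    "trait_causal_variant": genotypes.variants["id"].iloc[cidx],
                    "shared_with_eqtl": shared,
                }
            )
        causal_idx = np.asarray(causal_idx, dtype=int)
    else:
        causal_idx = np.asarray([vid_to_idx[v] for v in causal_variants], dtype=int)

    z_mean = np.zeros(genotypes.n_variants)
    if causal_idx.size:
        causal_z = np.sqrt(config.gwas_n * config.gwas_var_explained) * np.where(
            rng.random(causal_idx.size) < 0.5, 1.0, -1.0
        )
        z_mean = _marginal_z_means(genotypes, causal_idx, causal_z)

    z_hat = z_mean + rng.standard_normal(genotypes.n_variants)
    beta_hat = z_hat * se
    pval = 2.0 * stats.norm.sf(np.abs(z_hat))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "id": genotypes.variants["id"],
            "chrom": genotypes.variants["chrom"],
            "pos": genotypes.variants["pos"],
            "beta": beta_hat,
            "se": se,
            "pvalue": pval,
            "n": config.gwas_n,
        }
    )
    keep = np.isfinite(se)
    gw = GwasSummary(trait, table.loc[keep].reset_index(drop=True))
    gw.planted = pd.DataFrame(planted_rows)
    return gw


def _low_ld_neighbor(
    genotypes: GenotypeMatrix, idx: int, rng: np.random.Generator,
    max_r2: float = 0.2, window: int = CIS_WINDOW,
    center_pos: int | None = None,
) -> int:
    """A variant in low pooled LD with ``idx`` within ``window`` of
    ``center_pos`` (default: of ``idx`` itself); falls back to farthest."""
    pos = genotypes.variants["pos"].to_numpy()
    center = pos[idx] if center_pos is None else center_pos
    near = np.flatnonzero(
        (np.abs(pos - center) <= window) & (np.arange(len(pos)) != idx)
    )
    if near.size == 0:
        near = np.flatnonzero(np.arange(len(pos)) != idx)
    d = genotypes.dosage[:, near].astype(float)
    s = genotypes.dosage[:, idx].astype(float)
    s = s - s.mean()
    d = d - d.mean(axis=0)
    denom = np.sqrt((d * d).sum(axis=0) * (s * s).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, ((d.T @ s) / denom) ** 2, 1.0)
    ok = near[r2 < max_r2]
    if ok.size == 0:
        return int(near[np.argmax(np.abs(pos[near] - pos[idx]))])
    return int(rng.choice(ok))


def simulate_study(config: SimConfig):
    """Convenience wrapper: genotypes, counts, truth, and one GWAS trait."""
    g = simulate_genotypes(config)
    expr, truth = simulate_expression(g, config)
    gwas = simulate_gwas(g, truth, config)
    return g, expr, truth, gwas
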