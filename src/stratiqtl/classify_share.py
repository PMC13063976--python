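"""eGene sharing classification and cross-breed effect-sharing metrics.

An eGene detected in exactly one breed (within a tissue) is
breed-specific; one detected in two or three breeds is breed-shared.
Effect sharing between breed pairs is quantified on empirical-Bayes
posterior means under sign and magnitude criteria (same direction;
within a factor of 2 or 4), restricted to effects whose local false
sign rate (LFSR) is below 0.05.  The shrinkage is condition-by-condition:
a normal-means mixture prior (point mass at zero plus zero-mean normals
on a geometric scale grid) fitted by EM per breed.

Also here: per-breed LD scores (sum of pairwise dosage r^2, self term
included), folded allele frequencies, and mean per-gene conservation
scores with the >= 50% coverage rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .containers import GenotypeMatrix, ScoreTrack

logger = logging.getLogger(__name__)

__all__ = [
    "classify_egenes",
    "classification_summary",
    "shrink_lfsr",
    "ShrinkageResult",
    "pairwise_sharing",
    "SharingEstimate",
    "ld_scores",
    "maf_by_breed",
    "gene_conservation",
    "LFSR_MAX",
]

LFSR_MAX = 0.05


def classify_egenes(
    egene_flags: dict[str, pd.DataFrame], tissue: str = ""
) -> pd.DataFrame:
    """Partition the tested gene universe into sharing categories.

    ``egene_flags`` maps breed -> DataFrame with ``gene_id`` and
    ``is_egene`` (one row per tested gene).  The universe is the union of
    tested genes; a gene untested in some breed is classified from the
    available flags (logged).  Output columns: ``gene_id, tissue``, one
    ``is_egene_<breed>`` per breed, and ``category`` in
    ``{shared3, shared2:<B1>+<B2>, specific:<B>, non_egene}``.
    """
    breeds = list(egene_flags)
    universe: list[str] = []
    seen = set()
    flag_maps = {}
    for b in breeds:
        df = egene_flags[b]
        flag_maps[b] = dict(zip(df["gene_id"], df["is_egene"]))
        for gid in df["gene_id"]:
            if gid not in seen:
                seen.add(gid)
                universe.append(gid)
    n_untested = 0
    rows = []
    for gid in universe:
        flags = {}
        for b in breeds:
            if gid in flag_maps[b]:
                flags[b] = bool(flag_maps[b][gid])
            else:
                flags[b] = False
                n_untested += 1
        pos = [b for b in breeds if flags[b]]
        if len(pos) == 0:
            cat = "non_egene"
        elif len(pos) == 1:
            cat = f"specific:{pos[0]}"
        elif len(pos) == 2:
            cat = f"shared2:{pos[0]}+{pos[1]}"
        else:
            cat = "shared3"
        rows.append(
            {
                "gene_id": gid,
                "tissue": tissue,
                **{f"is_egene_{b}": flags[b] for b in breeds},
                "category": cat,
            }
        )
    if n_untested:
        logger.info(
            "%d gene x breed combinations untested; treated as non-eGene there",
            n_untested,
        )
    return pd.DataFrame(rows)


def classification_summary(classification: pd.DataFrame) -> pd.DataFrame:
    """Per-breed eGene counts and shared fractions.

    The shared fraction of a breed is the proportion of that breed's
    eGenes also detected in at least one other breed.
    """
    breeds = [
        c.removeprefix("is_egene_")
        for c in classification.columns
        if c.startswith("is_egene_")
    ]
    rows = []
    for b in breeds:
        mine = classification[classification[f"is_egene_{b}"]]
        n = len(mine)
        others = [f"is_egene_{o}" for o in breeds if o != b]
        shared = int(mine[others].any(axis=1).sum()) if n else 0
        rows.append(
            {
                "breed": b,
                "n_egenes": n,
                "n_shared": shared,
                "n_specific": n - shared,
                "shared_fraction": shared / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ShrinkageResult:
    posterior_mean: np.ndarray
    lfsr: np.ndarray
    mixture_sd: np.ndarray
    mixture_weights: np.ndarray
    converged: bool


def shrink_lfsr(
    betahat: np.ndarray,
    se: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> ShrinkageResult:
    """Empirical-Bayes normal-means shrinkage with local false sign rates.

    Prior: ``pi_0 delta_0 + sum_k pi_k N(0, tau_k^2)`` with ``tau_k`` on a
    geometric grid from ``min(se)/10`` to ``2 max|betahat|``; weights by EM
    on the marginal likelihood ``betahat_j ~ N(0, se_j^2 + tau_k^2)``.
    ``lfsr_j = min(P(b_j >= 0 | data), P(b_j <= 0 | data))``, both sides
    including the point mass at zero.
    """
    betahat = np.asarray(betahat, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if betahat.shape != se.shape:
        raise ValueError("betahat and se must have equal length")
    n = betahat.size
    lo = se.min() / 10.0
    hi = max(2.0 * np.abs(betahat).max(), lo * 2.0)
    n_grid = max(int(np.ceil(np.log2(hi / lo))) + 1, 2)
    tau = np.concatenate([[0.0], np.geomspace(lo, hi, n_grid)])
    k = tau.size

    # marginal log-likelihood of each observation under each component
    var = se[:, None] ** 2 + tau[None, :] ** 2
    loglik = -0.5 * (np.log(2.0 * np.pi * var) + betahat[:, None] ** 2 / var)

    pi = np.full(k, 1.0 / k)
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        logpost = np.log(np.clip(pi, 1e-300, None))[None, :] + loglik
        norm = logsumexp(logpost, axis=1)
        resp = np.exp(logpost - norm[:, None])
        pi = resp.mean(axis=0)
        cur = norm.sum()
        if cur - prev < tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = cur
    if not converged:
        logger.warning("shrinkage EM did not converge in %d iterations", max_iter)

    # per-observation posterior: mixture of normals (+ point mass)
    logpost = np.log(np.clip(pi, 1e-300, None))[None, :] + loglik
    resp = np.exp(logpost - logsumexp(logpost, axis=1)[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = tau[None, :] ** 2 / var  # posterior mean multiplier per comp.
    post_mu = shrink * betahat[:, None]
    post_var = (se[:, None] ** 2) * shrink
    post_mean = (resp * post_mu).sum(axis=1)

    sd = np.sqrt(post_var[:, 1:])
    p_neg_comp = stats.norm.cdf(0.0, loc=post_mu[:, 1:], scale=sd)
    p_neg = resp[:, 0] + (resp[:, 1:] * p_neg_comp).sum(axis=1)
    p_pos = resp[:, 0] + (resp[:, 1:] * (1.0 - p_neg_comp)).sum(axis=1)
    lfsr = np.minimum(p_neg, p_pos)
    return ShrinkageResult(post_mean, lfsr, tau, pi, converged)


@dataclass
class SharingEstimate:
    breed_pair: tuple[str, str]
    n_effects: int
    prop_sign: float
    prop_mag2: float
    prop_mag4: float

    def __post_init__(self) -> None:
        if not (
            self.prop_mag2 <= self.prop_mag4 + 1e-12
            and self.prop_mag4 <= self.prop_sign + 1e-12
            and self.prop_sign <= 1.0 + 1e-12
        ):
            raise ValueError("sharing proportions must satisfy mag2 <= mag4 <= sign <= 1")


def pairwise_sharing(
    effects: pd.DataFrame,
    breed_pair: tuple[str, str],
    lfsr_gate: str = "either",
    use_posterior: bool = True,
) -> SharingEstimate:
    """Sign/magnitude effect sharing between two breeds.

    ``effects`` carries one row per shared eGene with columns
    ``beta_<B>, lfsr_<B>`` (and ``raw_beta_<B>`` when
    ``use_posterior=False``) for each breed of the pair.  Effects enter
    when LFSR < 0.05 in at least one breed (``lfsr_gate='both'`` requires
    both).  ``prop_sign`` is the fraction with concordant direction;
    ``prop_magK`` additionally requires the magnitude ratio <= K.
    """
    b1, b2 = breed_pair
    col = "beta_" if use_posterior else "raw_beta_"
    l1 = effects[f"lfsr_{b1}"].to_numpy()
    l2 = effects[f"lfsr_{b2}"].to_numpy()
    if lfsr_gate == "either":
        gate = (l1 < LFSR_MAX) | (l2 < LFSR_MAX)
    elif lfsr_gate == "both":
        gate = (l1 < LFSR_MAX) & (l2 < LFSR_MAX)
    else:
        raise ValueError(f"unknown lfsr_gate {lfsr_gate!r}")
    x = effects.loc[gate, f"{col}{b1}"].to_numpy()
    y = effects.loc[gate, f"{col}{b2}"].to_numpy()
    if x.size == 0:
        raise ValueError(f"no effects pass the LFSR gate for pair {breed_pair}")
    same_sign = np.sign(x) == np.sign(y)
    same_sign &= (x != 0) & (y != 0)
    ax, ay = np.abs(x), np.abs(y)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(ax, ay) / np.minimum(ax, ay)
    mag2 = same_sign & (ratio <= 2.0)
    mag4 = same_sign & (ratio <= 4.0)
    return SharingEstimate(
        breed_pair=(b1, b2),
        n_effects=int(x.size),
        prop_sign=float(same_sign.mean()),
        prop_mag2=float(mag2.mean()),
        prop_mag4=float(mag4.mean()),
    )


def ld_scores(
    g: GenotypeMatrix, region: tuple[str, int, int], breed: str | None = None
) -> pd.DataFrame:
    """Per-variant LD score over a region: sum of pairwise dosage r^2.

    The self term contributes 1, so scores are >= 1.  Zero-variance
    variants in the region are excluded from both sides of the sum.
    ``region`` is (chrom, start, end), positions 1-based inclusive.
    """
    sub = g.for_breed(breed) if breed is not None else g
    if sub.n_samples < 2:
        raise ValueError("LD scores need at least 2 samples")
    chrom, start, end = region
    v = sub.variants
    mask = ((v["chrom"] == chrom) & (v["pos"] >= start) & (v["pos"] <= end)).to_numpy()
    idx = np.flatnonzero(mask)
    d = sub.dosage[:, idx].astype(float)
    sd = d.std(axis=0)
    poly = sd > 0
    if (~poly).any():
        logger.warning(
            "%d zero-variance variant(s) excluded from LD scores", int((~poly).sum())
        )
    dd = d[:, poly] - d[:, poly].mean(axis=0)
    norm = dd / np.sqrt((dd * dd).sum(axis=0))
    r = norm.T @ norm
    scores = (r * r).sum(axis=1)
    out = pd.DataFrame(
        {
            "variant_id": v["id"].to_numpy()[idx][poly],
            "ld_score": scores,
        }
    )
    if breed is not None:
        out["breed"] = breed
    return out


def maf_by_breed(g: GenotypeMatrix, variant_ids: list[str]) -> pd.DataFrame:
    """Folded allele frequency per breed for the named variants."""
    vid_to_idx = {v: i for i, v in enumerate(g.variants["id"])}
    missing = [v for v in variant_ids if v not in vid_to_idx]
    if missing:
        raise KeyError(f"unknown variants: {missing}")
    idx = [vid_to_idx[v] for v in variant_ids]
    breeds = list(dict.fromkeys(g.samples["breed"]))
    out = {"variant_id": list(variant_ids)}
    for b in breeds:
        sub = g.dosage[g.breed_mask(b)][:, idx]
        p = sub.mean(axis=0) / 2.0
        out[f"maf_{b}"] = np.minimum(p, 1.0 - p)
    return pd.DataFrame(out)


def gene_conservation(
    track: ScoreTrack, genes: pd.DataFrame, min_coverage: float = 0.5
) -> pd.DataFrame:
    """Mean per-base conservation score over each gene body.

    The gene body spans ``length`` bases from the TSS (1-based inclusive
    start; strand is ignored).  The mean is reported only when at least
    ``min_coverage`` of the gene's bases are covered by the track.
    Output columns: ``gene_id, mean_score, covered_fraction``.
    """
    iv = track.intervals
    rows = []
    for _, gene in genes.iterrows():
        length = int(gene["length"])
        if length <= 0:
            raise ValueError(f"gene {gene['id']} has non-positive length")
        g_start = int(gene["tss"]) - 1          # 0-based
        g_end = g_start + length                # half-open
        sub = iv[iv["chrom"] == gene["chrom"]]
        s = np.maximum(sub["start"].to_numpy(), g_start)
        e = np.minimum(sub["end"].to_numpy(), g_end)
        span = np.clip(e - s, 0, None)
        covered = int(span.sum())
        frac = covered / length
        if frac >= min_coverage and covered > 0:
            mean = float((span * sub["score"].to_numpy()).sum() / covered)
        else:
            mean = np.nan
        rows.append(
            {"gene_id": gene["id"], "mean_score": mean, "covered_fraction": frac}
        )
    return pd.DataFrame(rows)
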