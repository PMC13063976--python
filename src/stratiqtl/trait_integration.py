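"""GWAS integration: enrichment of trait signals in eGene regions and
eQTL–GWAS colocalization.

Enrichment uses a resampling statistic: significant GWAS SNPs
(p <= 5e-8) form the observed set; equal-sized control sets are drawn
without replacement from the non-significant SNPs; the fold enrichment
is the observed in-region proportion divided by the mean control
proportion, with a +1-smoothed empirical p-value.

Colocalization follows the standard single-causal-variant Bayesian
framework: a Wakefield approximate Bayes factor per SNP for each trait,
and posteriors over the five hypotheses (no signal / trait-1 only /
trait-2 only / distinct variants / shared variant) accumulated in log
space.  A gene-trait pair colocalizes when PP.H4 > 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import GwasSummary

logger = logging.getLogger(__name__)

__all__ = [
    "GWAS_SIG_P",
    "COLOC_H4_MIN",
    "filter_gwas_traits",
    "egene_regions",
    "in_regions",
    "enrichment_permutation",
    "EnrichmentResult",
    "wakefield_abf",
    "coloc_abf",
    "ColocResult",
]

GWAS_SIG_P = 5e-8
COLOC_H4_MIN = 0.8
REGION_HALF_WIDTH = 1_000_000


def filter_gwas_traits(traits: dict[str, GwasSummary]) -> dict[str, GwasSummary]:
    """Keep traits whose minimum p-value is <= 5e-8; drop empty traits."""
    kept = {}
    for name, gw in traits.items():
        if len(gw.table) == 0:
            logger.warning("trait %s has no records; dropped", name)
            continue
        if gw.min_p <= GWAS_SIG_P:
            kept[name] = gw
    return kept


def egene_regions(
    genes: pd.DataFrame, gene_ids: list[str] | None = None,
    half_width: int = REGION_HALF_WIDTH,
) -> pd.DataFrame:
    """Merged ``TSS +/- 1 Mb`` membership intervals for a set of eGenes.

    Intervals are clamped at position 1 and merged when overlapping, so a
    SNP between two nearby eGenes counts once.  Output columns:
    ``chrom, start, end`` (1-based inclusive).
    """
    sel = genes if gene_ids is None else genes[genes["id"].isin(set(gene_ids))]
    raw = pd.DataFrame(
        {
            "chrom": sel["chrom"].to_numpy(),
            "start": np.maximum(1, sel["tss"].to_numpy() - half_width),
            "end": sel["tss"].to_numpy() + half_width,
        }
    ).sort_values(["chrom", "start"])
    merged = []
    for chrom, grp in raw.groupby("chrom", sort=False):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def in_regions(
    chrom: np.ndarray, pos: np.ndarray, regions: pd.DataFrame
) -> np.ndarray:
    """Boolean membership of positions in merged 1-based inclusive regions."""
    out = np.zeros(len(pos), dtype=bool)
    for c, grp in regions.groupby("chrom", sort=False):
        m = np.asarray(chrom) == c
        if not m.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        p = np.asarray(pos)[m]
        # merged intervals are disjoint and sorted: searchsorted membership
        i = np.searchsorted(starts, p, side="right") - 1
        hit = (i >= 0) & (p <= ends[np.clip(i, 0, len(ends) - 1)])
        out[np.flatnonzero(m)] = hit
    return out


@dataclass
class EnrichmentResult:
    trait: str
    egene_category: str
    n_sig_snps: int
    observed_prop: float
    null_mean_prop: float
    fold: float
    empirical_p: float
    n_resamples: int


def enrichment_permutation(
    gwas: GwasSummary,
    regions: pd.DataFrame,
    n_resamples: int = 1000,
    seed: int = 0,
    egene_category: str = "",
) -> EnrichmentResult:
    """Fold enrichment of significant GWAS SNPs in eGene regions.

    Controls are equal-size draws without replacement from the
    non-significant SNPs; ``fold = observed_prop / mean(control props)``
    and ``empirical_p = (1 + #{control >= observed}) / (n_resamples + 1)``.
    """
    tab = gwas.table
    sig = (tab["pvalue"] <= GWAS_SIG_P).to_numpy()
    n_sig = int(sig.sum())
    if n_sig == 0:
        raise ValueError(f"trait {gwas.trait}: no significant SNPs at p <= {GWAS_SIG_P}")
    n_null = int((~sig).sum())
    if n_null == 0:
        raise ValueError(f"trait {gwas.trait}: empty non-significant pool")
    if n_null < n_sig:
        raise ValueError(
            f"trait {gwas.trait}: non-significant pool ({n_null}) smaller than "
            f"significant set ({n_sig})"
        )
    member = in_regions(tab["chrom"].to_numpy(), tab["pos"].to_numpy(), regions)
    observed = float(member[sig].mean())
    null_member = member[~sig]
    rng = np.random.default_rng(seed)
    null_props = np.empty(n_resamples)
    for r in range(n_resamples):
        pick = rng.choice(n_null, size=n_sig, replace=False)
        null_props[r] = null_member[pick].mean()
    null_mean = float(null_props.mean())
    fold = observed / null_mean if null_mean > 0 else np.inf
    emp_p = float((1 + np.sum(null_props >= observed)) / (n_resamples + 1))
    return EnrichmentResult(
        trait=gwas.trait, egene_category=egene_category, n_sig_snps=n_sig,
        observed_prop=observed, null_mean_prop=null_mean, fold=fold,
        empirical_p=emp_p, n_resamples=n_resamples,
    )


def wakefield_abf(
    beta: np.ndarray, se: np.ndarray, prior_sd: float = 0.15
) -> np.ndarray:
    """Log approximate Bayes factor (alternative vs null) per SNP.

    With ``V = se^2``, ``W = prior_sd^2``, ``r = W / (V + W)`` and
    ``z = beta / se``: ``log_abf = 0.5 log(1 - r) + 0.5 r z^2``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    if np.any(se <= 0) or not (np.all(np.isfinite(beta)) and np.all(np.isfinite(se))):
        raise ValueError("beta/se must be finite with se > 0")
    v = se ** 2
    w = prior_sd ** 2
    r = w / (v + w)
    z = beta / se
    return 0.5 * np.log(1.0 - r) + 0.5 * r * z ** 2


@dataclass
class ColocResult:
    gene_id: str
    trait: str
    pp: dict[str, float]
    n_snps: int

    def __post_init__(self) -> None:
        total = sum(self.pp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posteriors sum to {total}, not 1")

    @property
    def colocalized(self) -> bool:
        return self.pp["H4"] > COLOC_H4_MIN


def coloc_abf(
    eqtl_stats: pd.DataFrame,
    gwas_stats: pd.DataFrame,
    gene_id: str = "",
    trait: str = "",
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_eqtl: float = 0.15,
    prior_sd_gwas: float = 0.15,
) -> ColocResult:
    """Five-hypothesis colocalization posteriors for one gene-trait pair.

    Both inputs need columns ``id, beta, se``; SNPs are matched on ``id``.
    Under a single causal variant per trait, per-configuration ABFs are
    accumulated by log-sum-exp:

    * H1/H2: one trait has a causal SNP; * H3: both, at different SNPs;
    * H4: both, at the same SNP; H0 carries the remaining mass.
    """
    merged = eqtl_stats.merge(gwas_stats, on="id", suffixes=("_e", "_g"))
    if len(merged) == 0:
        raise ValueError(f"gene {gene_id}: no shared SNPs between eQTL and GWAS")
    l1 = wakefield_abf(merged["beta_e"], merged["se_e"], prior_sd_eqtl)
    l2 = wakefield_abf(merged["beta_g"], merged["se_g"], prior_sd_gwas)
    lsum = l1 + l2

    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(lsum)
    lh0 = 0.0
    lh1 = np.log(p1) + lse1
    lh2 = np.log(p2) + lse2
    # sum over i != j of exp(l1_i + l2_j) = exp(lse1 + lse2) - sum exp(l1+l2)
    both = lse1 + lse2
    lh3_body = both + np.log1p(-np.exp(np.minimum(lse12 - both, 0.0)))
    if not np.isfinite(lh3_body):  # single-SNP region: H3 impossible
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + lh3_body
    lh4 = np.log(p12) + lse12

    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(logs - logsumexp(logs))
    post = post / post.sum()
    pp = {f"H{i}": float(post[i]) for i in range(5)}
    return ColocResult(gene_id=gene_id, trait=trait, pp=pp, n_snps=len(merged))
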