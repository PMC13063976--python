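"""Genotype QC and the expression normalization chain.

Genotype filters come in two stages with deliberately different
boundaries: the pooled stage keeps MAF >= 0.05 and MAC >= 6 across all
samples; the per-breed stage keeps, within each breed, MAF > 0.01
(strict), MAC > 6 (strict) and heterozygote fraction < 0.99, then
intersects the surviving variant sets across breeds.

Expression travels counts -> TPM -> low-expression filter -> TMM -> INT.
TMM follows the trimmed mean of M-values scheme: gene-wise log2 ratios
against a reference sample, double trimming (30% on M, 5% on A),
inverse-asymptotic-variance weights, and factors rescaled to unit
geometric mean.  The inverse normal transform uses Blom offsets,
``Phi^-1((rank - 3/8) / (n + 1/4))``, with average ranks for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .containers import GenotypeMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "CovariateSet",
    "genotype_qc",
    "counts_to_tpm",
    "filter_low_expressed",
    "tmm_normalize",
    "inverse_normal_transform",
    "select_expression_pcs",
]

POOLED_MAF_MIN = 0.05   # inclusive
POOLED_MAC_MIN = 6      # inclusive
BREED_MAF_MIN = 0.01    # strict
BREED_MAC_MIN = 6       # strict
BREED_HET_MAX = 0.99    # strict
LOW_EXPR_TPM = 0.1
LOW_EXPR_FRAC = 0.80    # removed when the low fraction strictly exceeds this


@dataclass
class QcReport:
    """Per-filter removal counts plus the thresholds applied."""

    stage: str
    n_input: int
    n_output: int
    removed: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total_removed = self.n_input - self.n_output
        if total_removed < 0:
            raise ValueError("output larger than input")


def _variant_stats(dosage: np.ndarray):
    n = dosage.shape[0]
    alt = dosage.sum(axis=0)
    p = alt / (2.0 * n)
    maf = np.minimum(p, 1.0 - p)
    mac = np.minimum(alt, 2 * n - alt)
    het = (dosage == 1).mean(axis=0)
    return maf, mac, het


def genotype_qc(
    g: GenotypeMatrix, stage: str = "pooled"
) -> tuple[GenotypeMatrix, QcReport]:
    """Variant QC at the pooled or per-breed stage.

    ``pooled`` keeps variants with MAF >= 0.05 and MAC >= 6 across all
    samples.  ``per_breed`` applies MAF > 0.01, MAC > 6 and het < 0.99
    within every breed and keeps the intersection.
    """
    if stage == "pooled":
        maf, mac, _ = _variant_stats(g.dosage)
        keep = (maf >= POOLED_MAF_MIN) & (mac >= POOLED_MAC_MIN)
        report = QcReport(
            stage="pooled",
            n_input=g.n_variants,
            n_output=int(keep.sum()),
            removed={
                "maf": int((maf < POOLED_MAF_MIN).sum()),
                "mac": int(((maf >= POOLED_MAF_MIN) & (mac < POOLED_MAC_MIN)).sum()),
            },
            thresholds={"maf_min": POOLED_MAF_MIN, "mac_min": POOLED_MAC_MIN},
        )
    elif stage == "per_breed":
        breeds = list(dict.fromkeys(g.samples["breed"]))
        keep = np.ones(g.n_variants, dtype=bool)
        removed = {}
        for b in breeds:
            sub = g.dosage[g.breed_mask(b), :]
            maf, mac, het = _variant_stats(sub)
            ok = (maf > BREED_MAF_MIN) & (mac > BREED_MAC_MIN) & (het < BREED_HET_MAX)
            removed[b] = int((~ok).sum())
            keep &= ok
        report = QcReport(
            stage="per_breed",
            n_input=g.n_variants,
            n_output=int(keep.sum()),
            removed=removed,
            thresholds={
                "maf_min_strict": BREED_MAF_MIN,
                "mac_min_strict": BREED_MAC_MIN,
                "het_max": BREED_HET_MAX,
            },
        )
    else:
        raise ValueError(f"unknown QC stage {stage!r}")
    return g.subset(variant_mask=keep), report


def counts_to_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts per million from raw counts and gene lengths.

    Per sample: length-normalized rates ``count / length_kb`` are scaled
    to sum to 1e6.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected counts, got {counts.unit}")
    lengths = counts.genes["length"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    rate = counts.values / (lengths[:, None] / 1000.0)
    totals = rate.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise ValueError(f"samples with zero total expression: {bad}")
    tpm = 1e6 * rate / totals[None, :]
    return counts.with_values(tpm, "TPM")


def filter_low_expressed(
    tpm: ExpressionMatrix,
    tpm_threshold: float = LOW_EXPR_TPM,
    max_low_fraction: float = LOW_EXPR_FRAC,
) -> tuple[ExpressionMatrix, QcReport]:
    """Drop genes with TPM <= 0.1 in more than 80% of samples (strict)."""
    if tpm.unit != "TPM":
        raise ValueError(f"expected TPM, got {tpm.unit}")
    low_frac = (tpm.values <= tpm_threshold).mean(axis=1)
    keep = low_frac <= max_low_fraction
    report = QcReport(
        stage="low_expression",
        n_input=tpm.n_genes,
        n_output=int(keep.sum()),
        removed={"low_expressed": int((~keep).sum())},
        thresholds={"tpm": tpm_threshold, "max_low_fraction": max_low_fraction},
    )
    return tpm.subset_genes(keep), report


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    logratio_trim: float = 0.30, abundance_trim: float = 0.05,
) -> float:
    """Two-sample TMM factor (log2 scale returned as 2**value)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.log2((obs / lib_obs) / (ref / lib_ref))
        a = 0.5 * np.log2((obs / lib_obs) * (ref / lib_ref))
    finite = np.isfinite(m) & np.isfinite(a) & (obs > 0) & (ref > 0)
    m, a = m[finite], a[finite]
    obs_f, ref_f = obs[finite], ref[finite]
    if m.size == 0:
        return 1.0
    # asymptotic (delta-method) variance of M per gene
    w = (lib_obs - obs_f) / (lib_obs * obs_f) + (lib_ref - ref_f) / (lib_ref * ref_f)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abundance_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = (m[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalize(
    counts: ExpressionMatrix, reference: str | None = None
) -> tuple[ExpressionMatrix, np.ndarray]:
    """TMM scaling factors and normalized counts-per-million.

    The reference defaults to the sample whose upper-quartile expression
    (of depth-scaled counts) is closest to the mean upper quartile.
    Factors are rescaled to unit geometric mean; normalized values are
    ``1e6 * counts / (library_size * factor)``.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected counts, got {counts.unit}")
    x = counts.values
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = [counts.sample_ids[i] for i in np.flatnonzero(lib <= 0)]
        raise ValueError(f"samples with zero library size: {bad}")
    if reference is None:
        uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = counts.sample_ids.index(reference)
    factors = np.array(
        [
            _tmm_pair_factor(x[:, j], x[:, ref_j], lib[j], lib[ref_j])
            for j in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    norm = 1e6 * x / (lib * factors)[None, :]
    return counts.with_values(norm, "TMM"), factors


def inverse_normal_transform(x: ExpressionMatrix) -> ExpressionMatrix:
    """Rank-based inverse normal transform per gene (Blom offsets).

    ``value = Phi^-1((rank - 3/8) / (n + 1/4))`` with average ranks for
    ties; invariant to any monotone transform of the input.
    """
    n = x.n_samples
    if n < 2:
        raise ValueError("inverse normal transform needs at least 2 samples")
    ranks = np.apply_along_axis(stats.rankdata, 1, x.values)
    out = ndtri((ranks - 3.0 / 8.0) / (n + 0.25))
    return x.with_values(out, "INT")


@dataclass
class CovariateSet:
    """Selected expression PCs with their variance-explained profile."""

    pcs: np.ndarray           # samples x k_selected
    pve: np.ndarray           # per-PC proportion of variance, all PCs
    k_selected: int
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.pve) > 1e-12):
            raise ValueError("per-PC variance shares must be non-increasing")
        if self.pve.sum() > 1.0 + 1e-9:
            raise ValueError("cumulative variance explained exceeds 1")


def _elbow_rule(
    pve: np.ndarray, increment_rule: str = "conjunction", rel_tol: float = 0.001
) -> int | None:
    """Smallest n whose next two variance-share increments fall below
    ``rel_tol`` of the cumulative share of the first n PCs; None if no n
    qualifies."""
    cum = np.cumsum(pve)
    for k in range(1, len(pve) - 1):
        inc1, inc2 = pve[k], pve[k + 1]
        bar = rel_tol * cum[k - 1]
        if increment_rule == "conjunction":
            ok = (inc1 < bar) and (inc2 < bar)
        elif increment_rule == "combined":
            ok = (inc1 + inc2) < bar
        else:
            raise ValueError(f"unknown increment_rule {increment_rule!r}")
        if ok:
            return k
    return None


def select_expression_pcs(
    tmm: ExpressionMatrix,
    increment_rule: str = "conjunction",
    rel_tol: float = 0.001,
    max_pcs: int = 10,
) -> CovariateSet:
    """Expression-PC covariates with an elbow rule on variance explained.

    PCs are computed on the gene-standardized matrix in sample space.  The
    smallest ``n >= 1`` is selected such that the variance-share increments
    of PCs ``n+1`` and ``n+2`` are each below ``rel_tol`` of the cumulative
    share of the first ``n`` PCs (``increment_rule='combined'`` instead
    compares their sum).  When no ``n`` qualifies, ``min(max_pcs,
    samples - 2)`` PCs are selected with a warning.

    The selection is capped at ``min(max_pcs, samples - 2)`` either way:
    on flat spectra the increment rule can otherwise fire only at the rank
    cliff of the spectrum and consume nearly all residual degrees of
    freedom.
    """
    if tmm.unit != "TMM":
        raise ValueError(f"expected TMM, got {tmm.unit}")
    n = tmm.n_samples
    if n < 4:
        raise ValueError("PC selection needs at least 4 samples")
    vals = tmm.values
    sd = vals.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("expression matrix has no variable genes")
    z = (vals[keep] - vals[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    # sample-space PCs via SVD of the genes x samples standardized matrix
    u, s, vt = np.linalg.svd(z - z.mean(axis=1, keepdims=True), full_matrices=False)
    ev = s ** 2
    pve = ev / ev.sum()
    pcs_all = vt.T * s[None, :]       # samples x components (scores)

    k_sel = _elbow_rule(pve, increment_rule, rel_tol)
    cap = min(max_pcs, n - 2)
    fallback = k_sel is None
    if fallback:
        k_sel = cap
        logger.warning(
            "PC elbow rule never fired; falling back to %d PCs", k_sel
        )
    elif k_sel > cap:
        logger.warning(
            "PC elbow rule selected %d PCs; capping at %d", k_sel, cap
        )
        k_sel = cap
    return CovariateSet(
        pcs=pcs_all[:, :k_sel], pve=pve, k_selected=k_sel, fallback_used=fallback
    )
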