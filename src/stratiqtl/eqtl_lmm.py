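"""Per-breed cis-eQTL mapping with a linear mixed model.

Model: ``y = X a + s b + g + e`` with ``g ~ N(0, G sg2)`` for the
genomic relationship matrix G (VanRaden normalization) and
``e ~ N(0, I se2)``.  The null model (no variant term) is fitted by REML
using the eigendecomposition of G, reducing the problem to a 1-D search
over the variance ratio; the cis scan then tests each variant in
``TSS +/- 1 Mb`` (inclusive) by generalized least squares in the rotated
space, with the variance *ratio* fixed at the null fit and the residual
scale re-estimated per variant (so the test reduces exactly to OLS when
G is the identity).

Gene-level p-values come from permutations of the expression vector; the
+1-smoothed empirical estimator is the default, with an optional
Beta-distribution fit to the permutation null.  eGenes are called at
Benjamini–Hochberg q < 0.05 across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .containers import GenotypeMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GrmMatrix",
    "LmmFit",
    "CisAssociation",
    "GeneEqtlSummary",
    "PermutationResult",
    "compute_grm",
    "fit_null_lmm",
    "test_cis",
    "permutation_gene_p",
    "call_egenes",
    "map_breed_eqtls",
    "CIS_WINDOW",
]

CIS_WINDOW = 1_000_000
EGENE_Q = 0.05
MIN_EIGENVALUE = 1e-8


@dataclass
class GrmMatrix:
    """Genomic relationship matrix ``G = M M' / (2 sum p_i (1 - p_i))``."""

    values: np.ndarray
    denom: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


def compute_grm(g: GenotypeMatrix) -> GrmMatrix:
    """GRM from mean-centered dosages of genome-wide variants.

    Monomorphic variants are disallowed: they contribute nothing to the
    denominator and indicate QC was skipped.
    """
    d = g.dosage.astype(float)
    p = d.mean(axis=0) / 2.0
    het = p * (1.0 - p)
    if np.any(het <= 0):
        bad = int(np.sum(het <= 0))
        raise ValueError(
            f"{bad} monomorphic variant(s) present; run genotype QC before the GRM"
        )
    m_centered = d - 2.0 * p[None, :]
    denom = 2.0 * float(het.sum())
    return GrmMatrix(m_centered @ m_centered.T / denom, denom)


@dataclass
class LmmFit:
    """Null-model REML fit plus the cached rotation reused by the scan."""

    sigma2_g: float
    sigma2_e: float
    alpha: np.ndarray
    loglik: float
    # rotation cache
    eigvals: np.ndarray = field(repr=False, default=None)
    eigvecs: np.ndarray = field(repr=False, default=None)
    gamma: float = field(repr=False, default=0.0)  # sigma2_g / sigma2_e
    x_rot: np.ndarray = field(repr=False, default=None)
    y_rot: np.ndarray = field(repr=False, default=None)
    y_raw: np.ndarray = field(repr=False, default=None)

    @property
    def heritability(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0


def _grm_eigh(grm: GrmMatrix) -> tuple[np.ndarray, np.ndarray]:
    w, v = np.linalg.eigh(grm.values)
    if w.min() < -1e-6:
        logger.warning(
            "GRM numerically non-PSD (min eigenvalue %.3g); flooring at %.0e",
            w.min(), MIN_EIGENVALUE,
        )
    return np.clip(w, MIN_EIGENVALUE, None), v


def _reml_neg_loglik(log_gamma: float, yr: np.ndarray, xr: np.ndarray,
                     d: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over both variances.

    With V = se2 * (gamma * D + I) in the rotated basis, se2 profiles out
    to the GLS residual mean square on n - c degrees of freedom.
    """
    gamma = np.exp(log_gamma)
    w = gamma * d + 1.0
    n, c = xr.shape
    xw = xr / w[:, None]
    xtwx = xr.T @ xw
    xtwy = xw.T @ yr
    try:
        alpha = np.linalg.solve(xtwx, xtwy)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yr - xr @ alpha
    rss = float(resid @ (resid / w))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - c)
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        (n - c) * np.log(2.0 * np.pi * sigma2)
        + np.log(w).sum()
        + logdet_xtwx
        + (n - c)
    )
    return -ll


def fit_null_lmm(
    y: np.ndarray,
    covariates: np.ndarray | None,
    grm: GrmMatrix,
    *,
    _eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> LmmFit:
    """REML fit of the variance components under the no-variant model.

    ``covariates`` are the expression-PC columns (an intercept is added
    here).  The search over the variance ratio runs on a bracketed
    log-scale grid refined by golden-section.  Pass ``_eig`` to reuse a
    precomputed GRM eigendecomposition across genes.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not np.all(np.isfinite(y)):
        raise ValueError("expression vector contains non-finite values")
    if covariates is None:
        x = np.ones((n, 1))
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            raise ValueError("covariate rows must match sample count")
        x = np.column_stack([np.ones(n), covariates])
    if grm.n != n:
        raise ValueError(f"GRM dimension {grm.n} != sample count {n}")

    d, u = _eig if _eig is not None else _grm_eigh(grm)
    yr = u.T @ y
    xr = u.T @ x

    grid = np.linspace(-10.0, 10.0, 41)
    vals = np.array([_reml_neg_loglik(lg, yr, xr, d) for lg in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _reml_neg_loglik, args=(yr, xr, d), bounds=(lo, hi),
        method="bounded", options={"xatol": 1e-8},
    )
    log_gamma = float(res.x) if res.fun <= vals[i] else float(grid[i])
    gamma = np.exp(log_gamma)

    w = gamma * d + 1.0
    xw = xr / w[:, None]
    xtwx = xr.T @ xw
    alpha = np.linalg.solve(xtwx, xw.T @ yr)
    resid = yr - xr @ alpha
    sigma2_e = float(resid @ (resid / w)) / (n - x.shape[1])
    sigma2_g = gamma * sigma2_e
    # treat a ratio at the lower search edge as a zero genetic component
    if log_gamma <= -10.0 + 1e-9:
        sigma2_g = 0.0
    loglik = -_reml_neg_loglik(log_gamma, yr, xr, d)
    return LmmFit(
        sigma2_g=sigma2_g, sigma2_e=sigma2_e, alpha=alpha, loglik=loglik,
        eigvals=d, eigvecs=u, gamma=gamma, x_rot=xr, y_rot=yr, y_raw=y,
    )


@dataclass
class CisAssociation:
    gene_id: str
    variant_id: str
    beta: float
    se: float
    p_nominal: float


@dataclass
class GeneEqtlSummary:
    """Per-gene mapping summary; ``q_value``/``is_egene`` filled by
    :func:`call_egenes`."""

    gene_id: str
    lead_variant: str
    lead_beta: float
    lead_se: float
    min_p_nominal: float
    p_gene: float
    q_value: float = np.nan
    variant_threshold: float = np.nan
    is_egene: bool = False
    perm_min_p: np.ndarray | None = field(repr=False, default=None)


def _residualize(fit: LmmFit, m_rot: np.ndarray) -> np.ndarray:
    """Project rotated columns off the covariates in the 1/w inner product."""
    w = fit.gamma * fit.eigvals + 1.0
    xr = fit.x_rot
    xw = xr / w[:, None]
    coef = np.linalg.solve(xr.T @ xw, xw.T @ m_rot)
    return m_rot - xr @ coef


def _gls_scan(fit: LmmFit, s_rot_resid: np.ndarray, y_rot_resid: np.ndarray):
    """Vectorized per-variant GLS with the variance ratio held at the null.

    Returns (beta, se, t, dof) for each variant column against each
    response column; residual scale is re-estimated per variant so the
    statistic is an exact t under G = I.
    """
    w = fit.gamma * fit.eigvals + 1.0
    n, c = fit.x_rot.shape
    dof = n - c - 1
    sw = s_rot_resid / w[:, None]
    num = sw.T @ y_rot_resid              # (m, k)
    den = np.einsum("ij,ij->j", s_rot_resid, sw)  # (m,)
    yy = np.einsum("ij,ij->j", y_rot_resid, y_rot_resid / w[:, None])  # (k,)
    den = np.where(den > 0, den, np.nan)
    beta = num / den[:, None]
    rss = yy[None, :] - num * beta
    rss = np.clip(rss, 1e-300, None)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 / den[:, None])
    t = beta / se
    return beta, se, t, dof


def cis_variant_mask(genotypes: GenotypeMatrix, tss: int, chrom: str,
                     window: int = CIS_WINDOW) -> np.ndarray:
    v = genotypes.variants
    return (
        (v["chrom"] == chrom)
        & (v["pos"] >= tss - window)
        & (v["pos"] <= tss + window)
    ).to_numpy()


def test_cis(
    gene: pd.Series,
    genotypes: GenotypeMatrix,
    fit: LmmFit,
    window: int = CIS_WINDOW,
) -> list[CisAssociation]:
    """Wald tests for every variant within ``window`` of the gene's TSS.

    Both window boundaries are inclusive.  Dosages are mean-centered; the
    variance ratio is fixed at the null fit.
    """
    mask = cis_variant_mask(genotypes, int(gene["tss"]), str(gene["chrom"]), window)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        logger.info("gene %s has no cis variants in +/- %d bp", gene["id"], window)
        return []
    s = genotypes.dosage[:, idx].astype(float)
    s -= s.mean(axis=0)
    s_rot = fit.eigvecs.T @ s
    s_res = _residualize(fit, s_rot)
    y_res = _residualize(fit, fit.y_rot[:, None])
    beta, se, t, dof = _gls_scan(fit, s_res, y_res)
    p = 2.0 * stats.t.sf(np.abs(t[:, 0]), dof)
    out = []
    vids = genotypes.variants["id"].to_numpy()
    for j, vi in enumerate(idx):
        out.append(
            CisAssociation(
                gene_id=str(gene["id"]), variant_id=str(vids[vi]),
                beta=float(beta[j, 0]), se=float(se[j, 0]),
                p_nominal=float(max(p[j], np.finfo(float).tiny)),
            )
        )
    return out


@dataclass
class PermutationResult:
    p_gene: float
    min_p_observed: float
    perm_min_p: np.ndarray = field(repr=False, default=None)


def permutation_gene_p(
    gene: pd.Series,
    genotypes: GenotypeMatrix,
    fit: LmmFit,
    k_perm: int = 1000,
    seed: int = 0,
    smoothing: str = "empirical",
    window: int = CIS_WINDOW,
) -> PermutationResult:
    """Gene-level p-value from permutations of the expression vector.

    Each permutation shuffles the raw expression vector, rotates it, and
    re-runs the fixed-ratio scan (no REML refit); the minimum nominal p
    is recorded.  ``p_gene`` is the +1-smoothed empirical tail
    probability; ``smoothing='beta'`` instead fits a Beta distribution to
    the permutation minima by maximum likelihood.
    """
    if k_perm < 100:
        raise ValueError(f"k_perm must be >= 100, got {k_perm}")
    mask = cis_variant_mask(genotypes, int(gene["tss"]), str(gene["chrom"]), window)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return PermutationResult(np.nan, np.nan, np.empty(0))
    s = genotypes.dosage[:, idx].astype(float)
    s -= s.mean(axis=0)
    s_rot = fit.eigvecs.T @ s
    s_res = _residualize(fit, s_rot)

    y_res = _residualize(fit, fit.y_rot[:, None])
    _, _, t_obs, dof = _gls_scan(fit, s_res, y_res)
    min_p_obs = float(2.0 * stats.t.sf(np.abs(t_obs).max(), dof))

    rng = np.random.default_rng(seed)
    n = fit.y_raw.size
    perm = np.empty((n, k_perm))
    for k in range(k_perm):
        perm[:, k] = fit.y_raw[rng.permutation(n)]
    y_rot = fit.eigvecs.T @ perm
    y_resid = _residualize(fit, y_rot)
    _, _, t, dof = _gls_scan(fit, s_res, y_resid)
    tmax = np.nanmax(np.abs(t), axis=0)
    perm_min_p = 2.0 * stats.t.sf(tmax, dof)

    if smoothing == "beta":
        a, b, _, _ = stats.beta.fit(
            np.clip(perm_min_p, 1e-12, 1 - 1e-12), floc=0.0, fscale=1.0
        )
        p_gene = float(stats.beta.cdf(min_p_obs, a, b))
        p_gene = max(p_gene, np.finfo(float).tiny)
    elif smoothing == "empirical":
        p_gene = (1.0 + np.sum(perm_min_p <= min_p_obs)) / (k_perm + 1.0)
    else:
        raise ValueError(f"unknown smoothing {smoothing!r}")
    return PermutationResult(float(p_gene), min_p_obs, perm_min_p)


def call_egenes(summaries: list[GeneEqtlSummary]) -> list[GeneEqtlSummary]:
    """BH correction across genes and eGene calling at q < 0.05.

    For eGenes, the variant-level nominal-p cutoff is the empirical
    quantile of the gene's permutation minima at the gene-level p
    corresponding to the q = 0.05 boundary (the largest significant
    ``p_gene``); variants below it are the gene's significant cis-eQTLs.
    """
    if not summaries:
        raise ValueError("no gene summaries to correct")
    p = np.array([s.p_gene for s in summaries])
    rej, q, _, _ = multipletests(p, alpha=EGENE_Q, method="fdr_bh")
    sig_p = p[q < EGENE_Q]
    p_star = float(sig_p.max()) if sig_p.size else np.nan
    for s, qi in zip(summaries, q):
        s.q_value = float(qi)
        s.is_egene = bool(qi < EGENE_Q)
        if s.is_egene and s.perm_min_p is not None and s.perm_min_p.size:
            s.variant_threshold = float(np.quantile(s.perm_min_p, p_star))
        else:
            s.variant_threshold = np.nan
    return summaries


def map_breed_eqtls(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    covariates: np.ndarray | None,
    grm: GrmMatrix,
    k_perm: int = 1000,
    seed: int = 0,
    window: int = CIS_WINDOW,
    smoothing: str = "empirical",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map every gene of one breed x tissue; returns (summaries, associations).

    ``expression`` must be INT-transformed and sample-aligned with
    ``genotypes``.  The GRM eigendecomposition is shared across genes; the
    permutation stream for gene *i* is seeded with ``seed + i`` so results
    do not depend on evaluation order.
    """
    if expression.unit != "INT":
        raise ValueError("eQTL mapping expects INT-transformed expression")
    if list(expression.sample_ids) != list(genotypes.samples["id"]):
        raise ValueError("expression and genotype samples are not aligned")
    eig = _grm_eigh(grm)
    summaries: list[GeneEqtlSummary] = []
    assoc_rows = []
    for gi in range(expression.n_genes):
        gene = expression.genes.iloc[gi]
        y = expression.values[gi, :]
        fit = fit_null_lmm(y, covariates, grm, _eig=eig)
        assocs = test_cis(gene, genotypes, fit, window=window)
        if not assocs:
            continue
        best = min(assocs, key=lambda a: a.p_nominal)
        perm = permutation_gene_p(
            gene, genotypes, fit, k_perm=k_perm, seed=seed + gi,
            smoothing=smoothing, window=window,
        )
        summaries.append(
            GeneEqtlSummary(
                gene_id=best.gene_id, lead_variant=best.variant_id,
                lead_beta=best.beta, lead_se=best.se,
                min_p_nominal=best.p_nominal, p_gene=perm.p_gene,
                perm_min_p=perm.perm_min_p,
            )
        )
        assoc_rows.extend(
            (a.gene_id, a.variant_id, a.beta, a.se, a.p_nominal) for a in assocs
        )
    call_egenes(summaries)
    summary_df = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in summaries],
            "lead_variant": [s.lead_variant for s in summaries],
            "lead_beta": [s.lead_beta for s in summaries],
            "lead_se": [s.lead_se for s in summaries],
            "min_p_nominal": [s.min_p_nominal for s in summaries],
            "p_gene": [s.p_gene for s in summaries],
            "q_value": [s.q_value for s in summaries],
            "variant_threshold": [s.variant_threshold for s in summaries],
            "is_egene": [s.is_egene for s in summaries],
        }
    )
    assoc_df = pd.DataFrame(
        assoc_rows, columns=["gene_id", "variant_id", "beta", "se", "p_nominal"]
    )
    return summary_df, assoc_df
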