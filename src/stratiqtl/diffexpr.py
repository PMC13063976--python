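"""One-vs-rest differential expression across breeds within a tissue.

Each gene is compared between one target breed and the pooled other two
breeds on ``log2(TPM + 1)``: the fold change is the difference of group
means, significance comes from a pooled-variance two-sided t-test with
Benjamini–Hochberg correction across genes, and a gene is flagged when
``|log2FC| > 1`` and ``FDR < 0.05``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = ["differential_expression", "LOG2FC_MIN", "DE_FDR"]

LOG2FC_MIN = 1.0
DE_FDR = 0.05


def differential_expression(
    tpm: ExpressionMatrix,
    breeds: pd.Series | np.ndarray,
    target_breed: str,
) -> pd.DataFrame:
    """Target-vs-rest DE table with columns
    ``gene_id, log2fc, t_statistic, pvalue, fdr, significant``."""
    if tpm.unit != "TPM":
        raise ValueError(f"expected TPM, got {tpm.unit}")
    breeds = np.asarray(breeds)
    if breeds.size != tpm.n_samples:
        raise ValueError("breed labels must match expression samples")
    target = breeds == target_breed
    if not target.any():
        raise ValueError(f"no samples for breed {target_breed!r}")
    if target.sum() < 2 or (~target).sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    logx = np.log2(tpm.values + 1.0)
    a = logx[:, target]
    b = logx[:, ~target]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    t_stat, pval = stats.ttest_ind(a, b, axis=1, equal_var=True)
    # zero-variance genes give nan; identical groups are by definition null
    pval = np.where(np.isfinite(pval), pval, 1.0)
    t_stat = np.where(np.isfinite(t_stat), t_stat, 0.0)
    _, fdr, _, _ = multipletests(pval, method="fdr_bh")
    significant = (np.abs(log2fc) > LOG2FC_MIN) & (fdr < DE_FDR)
    return pd.DataFrame(
        {
            "gene_id": tpm.genes["id"].to_numpy(),
            "log2fc": log2fc,
            "t_statistic": t_stat,
            "pvalue": pval,
            "fdr": fdr,
            "significant": significant,
        }
    )
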