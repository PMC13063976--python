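"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Genotypes are additive allele dosages in {0, 1, 2} coding the number of
  alternate alleles (0/1/2 = AA/Aa/aa).
* VCF, GWAS and gene-annotation coordinates are 1-based inclusive; score
  tracks (BED-like) are 0-based half-open.  Conversions between the two
  happen only in :mod:`stratiqtl.io_formats`.
* Expression values travel through explicit units: ``counts -> TPM -> TMM
  -> INT``; every transformation returns a new matrix tagged with its unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionMatrix",
    "GwasSummary",
    "ScoreTrack",
    "EXPRESSION_UNITS",
]

EXPRESSION_UNITS = ("counts", "TPM", "TMM", "INT")

#: Canonical breed labels of the three-population design.
BREEDS = ("Duroc", "Landrace", "Yorkshire")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant and sample metadata.

    Attributes
    ----------
    dosage
        ``(n_samples, n_variants)`` int8 array of alternate-allele dosages.
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt`` (pos 1-based).
    samples
        DataFrame with columns ``id, breed`` (extra columns allowed).
    """

    dosage: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (samples x variants)")
        n_s, n_v = self.dosage.shape
        if len(self.samples) != n_s:
            raise ValueError(
                f"sample metadata length {len(self.samples)} != dosage rows {n_s}"
            )
        if len(self.variants) != n_v:
            raise ValueError(
                f"variant metadata length {len(self.variants)} != dosage cols {n_v}"
            )
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"variant positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def breed_mask(self, breed: str) -> np.ndarray:
        mask = (self.samples["breed"] == breed).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown breed label: {breed!r}")
        return mask

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        d = self.dosage
        samples = self.samples
        variants = self.variants
        if sample_mask is not None:
            d = d[sample_mask, :]
            samples = samples.iloc[np.flatnonzero(np.asarray(sample_mask))] \
                if np.asarray(sample_mask).dtype == bool else samples.iloc[sample_mask]
            samples = samples.reset_index(drop=True)
        if variant_mask is not None:
            d = d[:, variant_mask]
            variants = variants.iloc[np.flatnonzero(np.asarray(variant_mask))] \
                if np.asarray(variant_mask).dtype == bool else variants.iloc[variant_mask]
            variants = variants.reset_index(drop=True)
        return GenotypeMatrix(d.copy(), variants, samples)

    def for_breed(self, breed: str) -> "GenotypeMatrix":
        return self.subset(sample_mask=self.breed_mask(breed))

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant."""
        return self.dosage.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a unit tag and gene annotation.

    ``genes`` carries ``id, chrom, tss, strand, length`` (tss 1-based;
    length in bp).  ``values`` rows align with ``genes``, columns with
    ``sample_ids``.
    """

    values: np.ndarray
    unit: str
    genes: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.genes)} genes, {len(self.sample_ids)} samples)"
            )
        if self.genes["id"].duplicated().any():
            dups = self.genes.loc[self.genes["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicated gene ids: {dups}")
        if self.unit in ("counts", "TPM") and np.any(self.values < 0):
            raise ValueError(f"{self.unit} values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return ExpressionMatrix(
            self.values[idx, :].copy(),
            self.unit,
            self.genes.iloc[idx].reset_index(drop=True),
            list(self.sample_ids),
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples absent from expression matrix: {missing}")
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, idx].copy(), self.unit, self.genes.copy(), list(sample_ids)
        )

    def with_values(self, values: np.ndarray, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, unit, self.genes.copy(), list(self.sample_ids))


@dataclass
class GwasSummary:
    """Single-trait GWAS summary statistics.

    ``table`` columns: ``id, chrom, pos, beta, se, pvalue, n`` with
    ``se > 0`` and ``pvalue`` in (0, 1].
    """

    trait: str
    table: pd.DataFrame

    REQUIRED = ("id", "chrom", "pos", "beta", "se", "pvalue", "n")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"GWAS table missing required column {col!r}")
        if (self.table["se"] <= 0).any():
            raise ValueError("GWAS table contains se <= 0")
        p = self.table["pvalue"]
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("GWAS p-values must lie in (0, 1]")

    @property
    def min_p(self) -> float:
        return float(self.table["pvalue"].min()) if len(self.table) else np.nan

    def zscores(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()


@dataclass
class ScoreTrack:
    """Per-base score intervals, BED-like: 0-based half-open, non-overlapping."""

    intervals: pd.DataFrame  # columns: chrom, start, end, score
    field: str = "score"

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "score"}
        if not need.issubset(self.intervals.columns):
            raise ValueError(f"score track needs columns {sorted(need)}")
        iv = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, grp in iv.groupby("chrom", sort=False):
            s = grp["start"].to_numpy()
            e = grp["end"].to_numpy()
            if np.any(e <= s):
                raise ValueError(f"empty/negative interval on {chrom}")
            if np.any(s[1:] < e[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
        self.intervals = iv
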