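"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are centralized here: VCF, GWAS and gene
annotation use 1-based inclusive positions; score tracks (bedGraph/BED)
use 0-based half-open intervals, so ``pos_1based = bed_start + 1``.

VCF handling targets a v4.2 subset: biallelic SNPs with a GT field.
Multi-allelic records are skipped (counted); sporadically missing
genotypes are imputed to the variant's mean dosage rounded to the
nearest integer (counted).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, GwasSummary, ScoreTrack

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_expression",
    "write_expression",
    "read_gwas",
    "write_gwas",
    "read_score_track",
    "write_score_track",
    "read_sample_map",
]

_GT_TO_DOSAGE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
                 "1/1": 2, "1|1": 2}
_MISSING_GT = {"./.", ".|.", "."}


def read_vcf(path: str | Path, sample_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Load biallelic GT records from a VCF into a dosage matrix.

    ``sample_map`` (columns ``id, breed``) attaches breed labels; samples
    without a label get breed ``"NA"``.  Multi-allelic records are
    skipped and counted; missing genotypes are mean-imputed (rounded)
    and counted.
    """
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    rows = []
    dosages = []
    n_multi = 0
    n_missing = 0
    prev = {}
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dos = np.where(gts == 3, 2, gts).astype(float)
        missing = gts == 2
        if missing.any():
            n_missing += int(missing.sum())
            obs = dos[~missing]
            fill = float(np.rint(obs.mean())) if obs.size else 0.0
            dos[missing] = fill
        chrom = rec.CHROM
        if chrom in prev and rec.POS <= prev[chrom]:
            raise ValueError(
                f"{path}: positions not strictly increasing at {chrom}:{rec.POS}"
            )
        prev[chrom] = rec.POS
        rows.append(
            {
                "id": rec.ID or f"{chrom}:{rec.POS}",
                "chrom": chrom,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        dosages.append(dos.astype(np.int8))
    vcf.close()
    if n_multi:
        logger.warning("%s: skipped %d multi-allelic record(s)", path, n_multi)
    if n_missing:
        logger.warning("%s: imputed %d missing genotype(s)", path, n_missing)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    dosage = np.stack(dosages, axis=1)
    variants = pd.DataFrame(rows)
    if sample_map is not None:
        lut = dict(zip(sample_map["id"], sample_map["breed"]))
        breeds = [lut.get(s, "NA") for s in sample_ids]
    else:
        breeds = ["NA"] * len(sample_ids)
    samples = pd.DataFrame({"id": sample_ids, "breed": breeds})
    gm = GenotypeMatrix(dosage, variants, samples)
    gm.n_multiallelic_skipped = n_multi
    gm.n_missing_imputed = n_missing
    return gm


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as an uncompressed VCF v4.2 with GT-only records."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stratiqtl\n")
        for chrom in dict.fromkeys(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples["id"])
            + "\n"
        )
        for j in range(g.n_variants):
            v = g.variants.iloc[j]
            gts = "\t".join(gt_str[int(d)] for d in g.dosage[:, j])
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_sample_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("id", "breed"):
        if col not in df.columns:
            raise ValueError(f"sample map missing required column {col!r}")
    return df


def write_expression(
    x: ExpressionMatrix, matrix_path: str | Path, annotation_path: str | Path
) -> None:
    """Expression TSV (unit tagged in a ``#unit=`` comment) + gene annotation."""
    with open(matrix_path, "w") as fh:
        fh.write(f"#unit={x.unit}\n")
        fh.write("gene_id\t" + "\t".join(x.sample_ids) + "\n")
        for gi in range(x.n_genes):
            vals = "\t".join(repr(float(v)) for v in x.values[gi, :])
            fh.write(f"{x.genes['id'].iloc[gi]}\t{vals}\n")
    x.genes.to_csv(annotation_path, sep="\t", index=False)


def read_expression(
    matrix_path: str | Path, annotation_path: str | Path
) -> ExpressionMatrix:
    """Read an expression TSV plus its gene-annotation companion.

    Errors name the offending gene (annotation mismatch) or row/column
    (non-numeric cell).
    """
    with open(matrix_path) as fh:
        first = fh.readline().strip()
        if first.startswith("#unit="):
            unit = first.removeprefix("#unit=")
            header = fh.readline()
        else:
            unit = "counts"
            header = first + "\n"
        sample_ids = header.rstrip("\n").split("\t")[1:]
        gene_ids = []
        values = []
        for row_i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            gene_ids.append(parts[0])
            row = np.empty(len(parts) - 1)
            for col_i, cell in enumerate(parts[1:]):
                try:
                    row[col_i] = float(cell)
                except ValueError:
                    raise ValueError(
                        f"{matrix_path}: non-numeric cell at data row {row_i + 1}, "
                        f"column {sample_ids[col_i]!r}: {cell!r}"
                    ) from None
            values.append(row)
    if len(set(gene_ids)) != len(gene_ids):
        dups = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ValueError(f"{matrix_path}: duplicated gene ids {dups}")
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    ann_ids = set(ann["id"])
    missing = [g for g in gene_ids if g not in ann_ids]
    if missing:
        raise ValueError(f"annotation missing gene(s): {missing}")
    ann = ann.set_index("id").loc[gene_ids].reset_index()
    return ExpressionMatrix(np.array(values), unit, ann, sample_ids)


def write_gwas(gw: GwasSummary, path: str | Path) -> None:
    gw.table.to_csv(path, sep="\t", index=False)


def read_gwas(path: str | Path, trait: str | None = None) -> GwasSummary:
    """Typed GWAS summary records; rows with se <= 0 or p outside (0, 1]
    are dropped with a logged count."""
    df = pd.read_csv(path, sep="\t")
    for col in GwasSummary.REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n0 = len(df)
    df = df[df["se"] > 0]
    n_bad_se = n0 - len(df)
    n1 = len(df)
    df = df[(df["pvalue"] > 0) & (df["pvalue"] <= 1)]
    n_bad_p = n1 - len(df)
    if n_bad_se:
        logger.warning("%s: dropped %d row(s) with se <= 0", path, n_bad_se)
    if n_bad_p:
        logger.warning("%s: dropped %d row(s) with p outside (0, 1]", path, n_bad_p)
    if trait is None:
        trait = Path(path).stem
    gw = GwasSummary(trait, df.reset_index(drop=True))
    gw.n_dropped_se = n_bad_se
    gw.n_dropped_p = n_bad_p
    return gw


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    track.intervals.to_csv(path, sep="\t", index=False, header=False)


def read_score_track(path: str | Path) -> ScoreTrack:
    """bedGraph-like track: chrom, start, end, score (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "score"],
        dtype={"chrom": str},
    )
    return ScoreTrack(df)
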