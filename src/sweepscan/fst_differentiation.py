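"""Per-SNP pairwise F_ST with MAF-binned empirical percentile ranking.

Uses the Weir & Cockerham (1984) variance-components estimator in its
haploid form (inputs are phased haplotypes, so there is no
heterozygosity term). Negative estimates are retained; clipping would
distort the empirical percentiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from sweepscan.genomic_io import GenomicIOError, HaplotypeMatrix

if TYPE_CHECKING:
    from sweepscan.empirical_calibration import EmpiricalNull

logger = logging.getLogger(__name__)

N_MAF_CLASSES = 50


def wc_fst(n1: int, p1: float, n2: int, p2: float) -> float:
    """Weir-Cockerham F_ST for two populations of haploid counts.

    n1, n2 are haplotype counts and p1, p2 allele frequencies. Returns
    NaN when both populations are fixed for the same allele (0/0).
    """
    if n1 < 2 or n2 < 2:
        raise GenomicIOError("need at least 2 haplotypes per population")
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise GenomicIOError("allele frequencies must lie in [0, 1]")
    n_bar = (n1 + n2) / 2.0
    n_c = 2.0 * n_bar - (n1**2 + n2**2) / (2.0 * n_bar)
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / n_bar
    t1 = s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - s2 / 2.0)
    t2 = ((n_c - 1.0) / (n_bar - 1.0)) * p_bar * (1.0 - p_bar) + (
        1.0 + (n_bar - n_c) / (n_bar - 1.0)
    ) * s2 / 2.0
    if t2 == 0.0:
        return math.nan
    return t1 / t2


def maf_bin(maf: float) -> int:
    """Map MAF in [0, 0.5] onto 50 classes of width 0.01; 0.5 -> bin 49."""
    if not (0.0 <= maf <= 0.5 + 1e-12):
        raise GenomicIOError(f"MAF {maf} outside [0, 0.5]; fold first")
    return min(int(math.floor(round(maf * 100.0, 9))), N_MAF_CLASSES - 1)


@dataclass
class FstRecord:
    variant_id: str
    chrom: str
    pos: int
    comparison: tuple[str, str]
    n1: int
    n2: int
    p1: float
    p2: float
    maf: float
    maf_bin: int
    fst: float
    rank: float = math.nan


def fst_records(
    matrix1: HaplotypeMatrix,
    matrix2: HaplotypeMatrix,
    comparison: tuple[str, str],
) -> list[FstRecord]:
    """Per-site F_ST over the shared site list of two population matrices.

    The matrices must carry identical site lists (the loader guarantees
    this when both are cut from one VCF). MAF is folded from the
    frequency pooled over the pair. Sites monomorphic in both
    populations (NaN F_ST) are excluded.
    """
    if [s.pos for s in matrix1.sites] != [s.pos for s in matrix2.sites]:
        raise GenomicIOError("population matrices must share the same site list")
    n1, n2 = matrix1.n_haplotypes, matrix2.n_haplotypes
    f1 = matrix1.allele_counts() / n1
    f2 = matrix2.allele_counts() / n2
    pooled = (matrix1.allele_counts() + matrix2.allele_counts()) / (n1 + n2)
    out: list[FstRecord] = []
    for j, site in enumerate(matrix1.sites):
        fst = wc_fst(n1, float(f1[j]), n2, float(f2[j]))
        if math.isnan(fst):
            continue
        maf = float(min(pooled[j], 1.0 - pooled[j]))
        out.append(
            FstRecord(
                variant_id=site.id,
                chrom=site.chrom,
                pos=site.pos,
                comparison=comparison,
                n1=n1,
                n2=n2,
                p1=float(f1[j]),
                p2=float(f2[j]),
                maf=maf,
                maf_bin=maf_bin(maf),
                fst=fst,
            )
        )
    return out


def fst_scan(
    matrix1: HaplotypeMatrix,
    matrix2: HaplotypeMatrix,
    comparison: tuple[str, str],
    null: "EmpiricalNull",
) -> list[FstRecord]:
    """Rank every biallelic SNP's F_ST within its MAF bin of the control null.

    Bins absent from the null, or below its minimum usable count, yield
    rank NaN with a warning.
    """
    records = fst_records(matrix1, matrix2, comparison)
    for rec in records:
        rank = null.rank(rec.fst, rec.maf_bin)
        if math.isnan(rank):
            logger.warning(
                "F_ST %s: MAF bin %d uncalibrated in null; rank NA",
                rec.variant_id, rec.maf_bin,
            )
        rec.rank = rank
    return records


def fst_records_to_tsv(records: list[FstRecord], path, header_comment: str = "") -> None:
    def fmt(x: float) -> str:
        return "NA" if math.isnan(x) else f"{x:.6g}"

    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment + "\n")
        fh.write(
            "variant_id\tchrom\tpos\tcomparison\tn1\tn2\tp1\tp2\tmaf\tmaf_bin\tfst\trank\n"
        )
        for r in records:
            fh.write(
                f"{r.variant_id}\t{r.chrom}\t{r.pos}\t{r.comparison[0]}/{r.comparison[1]}\t"
                f"{r.n1}\t{r.n2}\t{r.p1:.6g}\t{r.p2:.6g}\t{r.maf:.6g}\t{r.maf_bin}\t"
                f"{fmt(r.fst)}\t{fmt(r.rank)}\n"
            )
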