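"""The DIND test: intra-allelic diversity ratio over fixed flanking windows.

For a focal SNP, iPi_A (iPi_D) is the mean pairwise difference count
over a constant window of 40 flanking variants (20 up- and 20
downstream, the focal site excluded) among haplotypes carrying the focal
ancestral (derived) allele. DIND = iPi_A / iPi_D; when iPi_D = 0 the
value is a sentinel resolved batch-globally to max(finite DIND) + 20.
Calibration is empirical: DIND values are binned by DAF (100 classes)
against a control distribution; bins where >= 5% of control values are
sentinels cannot place a 95th percentile and are left uncalibrated.
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

N_DAF_CLASSES = 100
DEFAULT_FLANK = 20
SENTINEL_OFFSET = 20.0


def daf_bin(daf: float) -> int:
    """Map DAF in (0, 1) onto 100 right-closed classes ((k-1)/100, k/100].

    0.98 -> 97, 0.50 -> 49, 0.005 -> 0. DAF outside (0, 1) is an error
    (monomorphic sites are not tested).
    """
    if not (0.0 < daf < 1.0):
        raise GenomicIOError(f"DAF {daf} outside (0, 1)")
    return int(math.ceil(round(daf * N_DAF_CLASSES, 9))) - 1


@dataclass
class DindRecord:
    variant_id: str
    chrom: str
    pos: int
    population: str
    daf: float
    daf_bin: int
    i_pi_a: float
    i_pi_d: float
    dind: float  # NaN while sentinel-pending
    sentinel: bool
    rank: float = math.nan
    skip_reason: str = ""


def _mean_pairwise(block: np.ndarray) -> float:
    """Mean pairwise difference count over rows of a 0/1 block.

    A block with < 2 rows has undefined diversity; returns 0.0 (which,
    for the derived class, triggers the sentinel).
    """
    m = block.shape[0]
    if m < 2:
        return 0.0
    counts = block.sum(axis=0, dtype=np.float64)
    return float(np.sum(counts * (m - counts)) / (m * (m - 1) / 2.0))


def dind_statistic(
    matrix: HaplotypeMatrix, focal: int, flank: int = DEFAULT_FLANK
) -> tuple[float, float, float, bool]:
    """(iPi_A, iPi_D, dind, sentinel) for the focal site index.

    Requires >= ``flank`` polymorphic sites strictly before and after the
    focal site in the loaded region; raises otherwise (caller logs the
    skip). ``dind`` is NaN when the sentinel fires (resolve with
    :func:`resolve_sentinels`).
    """
    if not matrix.polarized:
        raise GenomicIOError("dind_statistic requires a polarized matrix")
    n = matrix.n_haplotypes
    counts = matrix.allele_counts()
    c_focal = int(counts[focal])
    if not (1 <= c_focal <= n - 1):
        raise GenomicIOError(f"focal site {focal} is monomorphic")
    poly = (counts > 0) & (counts < n)
    left = np.nonzero(poly[:focal])[0]
    right = np.nonzero(poly[focal + 1:])[0] + focal + 1
    if len(left) < flank or len(right) < flank:
        raise GenomicIOError(
            f"insufficient flanking variants for site {focal}: "
            f"{len(left)} upstream, {len(right)} downstream, need {flank} each"
        )
    flankers = np.concatenate([left[-flank:], right[:flank]])
    derived = matrix.data[:, focal] == 1
    block = matrix.data[:, flankers]
    i_pi_a = _mean_pairwise(block[~derived])
    i_pi_d = _mean_pairwise(block[derived])
    if i_pi_d == 0.0:
        return i_pi_a, i_pi_d, math.nan, True
    return i_pi_a, i_pi_d, i_pi_a / i_pi_d, False


def dind_records(
    matrix: HaplotypeMatrix,
    population: str,
    flank: int = DEFAULT_FLANK,
    site_indices: list[int] | None = None,
) -> list[DindRecord]:
    """Compute sentinel-pending DIND records for every eligible variant.

    Variants with insufficient flankers are emitted with a skip_reason
    and NaN values so that the run log accounts for every input site.
    """
    n = matrix.n_haplotypes
    dafs = matrix.derived_freqs()
    out: list[DindRecord] = []
    indices = site_indices if site_indices is not None else range(matrix.n_sites)
    for j in indices:
        site = matrix.sites[j]
        c = int(round(dafs[j] * n))
        if not (1 <= c <= n - 1):
            continue  # monomorphic: not a test site
        daf = float(dafs[j])
        try:
            i_pi_a, i_pi_d, dind, sentinel = dind_statistic(matrix, j, flank)
        except GenomicIOError as exc:
            out.append(
                DindRecord(
                    variant_id=site.id, chrom=site.chrom, pos=site.pos,
                    population=population, daf=daf, daf_bin=daf_bin(daf),
                    i_pi_a=math.nan, i_pi_d=math.nan, dind=math.nan,
                    sentinel=False, skip_reason=str(exc),
                )
            )
            continue
        out.append(
            DindRecord(
                variant_id=site.id, chrom=site.chrom, pos=site.pos,
                population=population, daf=daf, daf_bin=daf_bin(daf),
                i_pi_a=i_pi_a, i_pi_d=i_pi_d, dind=dind, sentinel=sentinel,
            )
        )
    return out


def resolve_sentinels(records: list[DindRecord]) -> list[DindRecord]:
    """Set every sentinel-pending DIND to max(finite DIND in batch) + 20.

    The batch must span the whole analysis data set (control + test
    variants together, one population); resolving per sub-batch would
    produce incomparable sentinel values.
    """
    finite = [r.dind for r in records if not r.skip_reason and not r.sentinel]
    pending = [r for r in records if r.sentinel]
    if pending and not finite:
        raise GenomicIOError("cannot resolve sentinels: no finite DIND value in batch")
    if pending:
        sentinel_value = max(finite) + SENTINEL_OFFSET
        for r in pending:
            r.dind = sentinel_value
    return records


def uncalibrated_bins(null: "EmpiricalNull", min_bin_count: int | None = None) -> set[int]:
    """DAF bins whose 95th percentile cannot discriminate.

    A bin is uncalibrated when >= 5% of its control values are sentinels
    (boundary inclusive) or when it holds fewer than ``min_bin_count``
    values (defaults to the null's own minimum).
    """
    if min_bin_count is None:
        min_bin_count = null.min_bin_count
    bad: set[int] = set()
    for b in range(N_DAF_CLASSES):
        values = null.bin_values(b)
        if len(values) < min_bin_count:
            bad.add(b)
            continue
        n_sent = null.sentinel_counts.get(b, 0)
        if n_sent / len(values) >= 0.05:
            bad.add(b)
    return bad


def dind_scan(
    records: list[DindRecord], null: "EmpiricalNull"
) -> list[DindRecord]:
    """Attach percentile ranks from the DAF-binned control null.

    Records in uncalibrated bins (or skipped records) keep rank NaN.
    Sentinels must already be resolved in both the records and the null.
    """
    bad_bins = uncalibrated_bins(null)
    for rec in records:
        if rec.skip_reason or math.isnan(rec.dind):
            continue
        if rec.daf_bin in bad_bins:
            rec.rank = math.nan
            rec.skip_reason = rec.skip_reason or "uncalibrated_daf_bin"
            continue
        rec.rank = null.rank(rec.dind, rec.daf_bin)
    return records


def dind_records_to_tsv(records: list[DindRecord], path, header_comment: str = "") -> None:
    def fmt(x: float) -> str:
        return "NA" if math.isnan(x) else f"{x:.6g}"

    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment + "\n")
        fh.write(
            "variant_id\tchrom\tpos\tpopulation\tdaf\tdaf_bin\ti_pi_a\ti_pi_d\t"
            "dind\tsentinel\trank\tskip_reason\n"
        )
        for r in records:
            fh.write(
                f"{r.variant_id}\t{r.chrom}\t{r.pos}\t{r.population}\t{r.daf:.6g}\t"
                f"{r.daf_bin}\t{fmt(r.i_pi_a)}\t{fmt(r.i_pi_d)}\t{fmt(r.dind)}\t"
                f"{int(r.sentinel)}\t{fmt(r.rank)}\t{r.skip_reason}\n"
            )
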