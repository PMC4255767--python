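"""Control-set empirical nulls, percentile ranks, and the combined caller.

The paper-style calibration machinery: statistics computed on a control
gene set are binned (MAF classes for F_ST, DAF classes for DIND, a
single pool for window DH), a test value's significance is its
percentile rank within its bin, and a region is called as a positive
selection target when, in one population, at least two statistics from
*different feature families* reach rank >= 0.95. Windows of normalized
Fay-Wu H below the control fifth percentile are attached as confirmatory
evidence only.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from sweepscan.dind_test import DindRecord
from sweepscan.fst_differentiation import FstRecord
from sweepscan.genomic_io import GenomicIOError
from sweepscan.sfs_stats import WindowStatRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_BIN_COUNT = 20
DEFAULT_RANK_THRESHOLD = 0.95
DEFAULT_DH_QUANTILE = 0.05

# Feature families for the combined-evidence rule. DH is deliberately
# absent: it is confirmatory only.
FAMILY_OF_STATISTIC = {
    "fst": "differentiation",
    "dind": "intra_allelic_diversity",
    "tajimas_d": "frequency_spectrum",
}


def percentile_rank(value: float, bin_array: Sequence[float] | np.ndarray) -> float:
    """rank = (# control values strictly below value) / (# control values).

    Ties count below (conservative). Empty bin -> NaN.
    """
    n = len(bin_array)
    if n == 0:
        return math.nan
    arr = np.asarray(bin_array, dtype=np.float64)
    if not np.all(arr[:-1] <= arr[1:]):
        arr = np.sort(arr)
    return bisect_left(arr.tolist(), value) / n


class EmpiricalNull:
    """Binned control-set distribution with percentile lookup.

    ``binning`` is ``("MAF", 50)``, ``("DAF", 100)`` or ``("none", 1)``;
    values land in bins supplied by the caller (the statistic modules own
    the bin functions). Sentinel counts are tracked per bin for the DIND
    calibration rule.
    """

    def __init__(
        self,
        statistic: str,
        binning: tuple[str, int],
        label: str = "",
        min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
    ):
        self.statistic = statistic
        self.binning = binning
        self.label = label  # population or comparison, free text
        self.min_bin_count = min_bin_count
        self._bins: dict[int, list[float]] = {}
        self._sorted: dict[int, np.ndarray] = {}
        self.sentinel_counts: dict[int, int] = {}
        self.n_ingested = 0
        self.n_excluded = 0

    def add(self, value: float, bin_index: int = 0, sentinel: bool = False) -> None:
        if math.isnan(value):
            self.n_excluded += 1
            return
        if not (0 <= bin_index < self.binning[1]):
            raise GenomicIOError(f"bin {bin_index} outside 0..{self.binning[1] - 1}")
        self._bins.setdefault(bin_index, []).append(float(value))
        if sentinel:
            self.sentinel_counts[bin_index] = self.sentinel_counts.get(bin_index, 0) + 1
        self._sorted.pop(bin_index, None)
        self.n_ingested += 1

    def bin_values(self, bin_index: int) -> np.ndarray:
        if bin_index not in self._sorted:
            self._sorted[bin_index] = np.sort(self._bins.get(bin_index, []))
        return self._sorted[bin_index]

    def bin_count(self, bin_index: int) -> int:
        return len(self._bins.get(bin_index, []))

    @property
    def n_values(self) -> int:
        return sum(len(v) for v in self._bins.values())

    def rank(self, value: float, bin_index: int = 0) -> float:
        """Percentile rank within the bin; NaN for unusable bins."""
        values = self.bin_values(bin_index)
        if len(values) < self.min_bin_count:
            return math.nan
        return percentile_rank(value, values)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# empirical_null statistic={self.statistic} "
                f"binning={self.binning[0]}:{self.binning[1]} label={self.label} "
                f"min_bin_count={self.min_bin_count} excluded={self.n_excluded}\n"
            )
            fh.write("bin\tvalue\tsentinel\n")
            for b in sorted(self._bins):
                n_sent = self.sentinel_counts.get(b, 0)
                values = self._bins[b]
                # sentinels were appended with their resolved value; mark
                # the largest n_sent values of the bin (sentinel value is
                # the batch maximum by construction)
                order = np.argsort(values, kind="stable")
                sentinel_set = set(order[len(values) - n_sent:]) if n_sent else set()
                for i, v in enumerate(values):
                    fh.write(f"{b}\t{v!r}\t{int(i in sentinel_set)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmpiricalNull":
        with open(path) as fh:
            meta = fh.readline()
            if not meta.startswith("# empirical_null"):
                raise GenomicIOError(f"{path}: not an empirical-null cache")
            kv = dict(tok.split("=", 1) for tok in meta[2:].split() if "=" in tok)
            var, n = kv["binning"].split(":")
            null = cls(
                statistic=kv["statistic"],
                binning=(var, int(n)),
                label=kv.get("label", ""),
                min_bin_count=int(kv.get("min_bin_count", DEFAULT_MIN_BIN_COUNT)),
            )
            null.n_excluded = int(kv.get("excluded", 0))
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["bin", "value", "sentinel"]:
                raise GenomicIOError(f"{path}: bad null cache header {header!r}")
            for line in fh:
                b, v, s = line.rstrip("\n").split("\t")
                null.add(float(v), int(b), sentinel=bool(int(s)))
        return null


def build_null(
    records: Iterable,
    statistic: str,
    binning: tuple[str, int],
    label: str = "",
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
) -> EmpiricalNull:
    """Route a control record stream into an EmpiricalNull.

    Accepts FstRecord (value=fst, bin=maf_bin), DindRecord (value=dind,
    bin=daf_bin, sentinel flag; skipped records excluded) or WindowStatRecord
    (value=DH, single bin). Raises on an empty stream.
    """
    null = EmpiricalNull(statistic, binning, label, min_bin_count)
    for rec in records:
        if isinstance(rec, FstRecord):
            null.add(rec.fst, rec.maf_bin)
        elif isinstance(rec, DindRecord):
            if rec.skip_reason:
                null.n_excluded += 1
                continue
            null.add(rec.dind, rec.daf_bin, sentinel=rec.sentinel)
        elif isinstance(rec, WindowStatRecord):
            null.add(rec.DH, 0)
        else:
            null.add(float(rec), 0)
    if null.n_values == 0:
        raise GenomicIOError("empty control stream: cannot build a null")
    logger.info(
        "build_null %s/%s: %d values in %d bins, %d excluded",
        statistic, label, null.n_values, len(null._bins), null.n_excluded,
    )
    return null


def dh_window_threshold(
    control_window_dh: Sequence[float] | np.ndarray, q: float = DEFAULT_DH_QUANTILE
) -> float:
    """Empirical q-quantile (linear interpolation) of control-window DH.

    Windows with DH below this threshold count as confirmatory sweep
    signals. Requires >= 100 control windows for a stable tail.
    """
    values = np.asarray(control_window_dh, dtype=np.float64)
    values = values[~np.isnan(values)]
    if len(values) < 100:
        raise GenomicIOError(f"need >= 100 control windows, got {len(values)}")
    return float(np.quantile(values, q, method="linear"))


@dataclass
class SelectionCall:
    region_label: str
    population: str
    supporting: list[tuple[str, str, float, float]] = field(default_factory=list)
    # (statistic, variant/window id, value, rank)
    confirmatory_windows: list[WindowStatRecord] = field(default_factory=list)
    verdict: bool = False
    rationale: str = ""


def _family(statistic: str) -> str:
    return FAMILY_OF_STATISTIC[statistic.split("[")[0]]


def combined_caller(
    region_label: str,
    fst_records: Sequence[FstRecord] = (),
    dind_records: Sequence[DindRecord] = (),
    window_records: Sequence[WindowStatRecord] = (),
    dh_threshold: float | None = None,
    tajima_site_ranks: Sequence[tuple[str, str, float, float]] = (),
    threshold: float = DEFAULT_RANK_THRESHOLD,
    same_variant: bool = True,
) -> list[SelectionCall]:
    """Combined-evidence positive-selection calls, one per population.

    Verdict is true when at least two statistics from different feature
    families reach rank >= threshold in the same population. By default
    (``same_variant=True``) the two statistics must concern the *same*
    variant — every reported candidate in the source analysis carries
    both a high DIND and a high F_ST rank — which keeps the neutral
    false-call rate near the joint-exceedance level; ``same_variant=False``
    relaxes this to region-level evidence pooling. An F_ST record from
    comparison (A, B) credits both A and B; its statistic tag names the
    comparison. DH windows below ``dh_threshold`` are attached as
    confirmatory evidence but never counted as primary support.
    ``tajima_site_ranks`` entries are (population, id, value, rank) with
    rank computed in the sweep-like direction.
    """
    support: dict[str, list[tuple[str, str, float, float]]] = {}

    for rec in fst_records:
        if not math.isnan(rec.rank) and rec.rank >= threshold:
            tag = f"fst[{rec.comparison[0]}/{rec.comparison[1]}]"
            for pop in rec.comparison:
                support.setdefault(pop, []).append(
                    (tag, rec.variant_id, rec.fst, rec.rank)
                )
    for rec in dind_records:
        if not math.isnan(rec.rank) and rec.rank >= threshold:
            support.setdefault(rec.population, []).append(
                ("dind", rec.variant_id, rec.dind, rec.rank)
            )
    for pop, vid, value, rank in tajima_site_ranks:
        if not math.isnan(rank) and rank >= threshold:
            support.setdefault(pop, []).append(("tajimas_d", vid, value, rank))

    confirmatory: dict[str, list[WindowStatRecord]] = {}
    if dh_threshold is not None:
        for w in window_records:
            if not math.isnan(w.DH) and w.DH < dh_threshold:
                confirmatory.setdefault(w.population, []).append(w)

    calls: list[SelectionCall] = []
    populations = sorted(set(support) | set(confirmatory))
    for pop in populations:
        sup = support.get(pop, [])
        if same_variant:
            by_variant: dict[str, set[str]] = {}
            for s, vid, _, _ in sup:
                by_variant.setdefault(vid, set()).add(_family(s))
            callers = {vid for vid, fams in by_variant.items() if len(fams) >= 2}
            verdict = bool(callers)
            n_fams = max((len(f) for f in by_variant.values()), default=0)
        else:
            fams = {_family(s) for s, *_ in sup}
            callers = {vid for _, vid, _, _ in sup}
            verdict = len(fams) >= 2
            n_fams = len(fams)
        if verdict:
            parts = [
                f"{s}:{vid} rank={rank:.3g}" for s, vid, _, rank in sup
                if vid in callers
            ]
            rationale = (
                f"{region_label}/{pop}: {n_fams} feature families at rank >= "
                f"{threshold}: " + "; ".join(parts)
            )
        else:
            rationale = (
                f"{region_label}/{pop}: no variant with >= 2 feature families at "
                f"rank >= {threshold}; no call"
            )
        conf = confirmatory.get(pop, [])
        if conf:
            rationale += f" [confirmatory: {len(conf)} DH window(s) below threshold]"
        calls.append(
            SelectionCall(
                region_label=region_label,
                population=pop,
                supporting=sup,
                confirmatory_windows=conf,
                verdict=verdict,
                rationale=rationale,
            )
        )
    return calls


def calls_to_tsv(calls: list[SelectionCall], path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment + "\n")
        fh.write("region\tpopulation\tverdict\tn_support\tn_confirmatory\trationale\n")
        for c in calls:
            fh.write(
                f"{c.region_label}\t{c.population}\t{int(c.verdict)}\t"
                f"{len(c.supporting)}\t{len(c.confirmatory_windows)}\t{c.rationale}\n"
            )
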