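"""Site-frequency-spectrum estimators and sliding-window machinery.

Implements pi (mean pairwise differences), Watterson's theta, Tajima's D
with the 1989 normalization constants, Zeng's theta_L, Fay-Wu's H
(= 2(pi - theta_L)) and its variance-normalized form DH, plus 5-kb /
500-bp sliding-window scans over a region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from sweepscan.genomic_io import GenomicIOError, HaplotypeMatrix, Region

DEFAULT_WINDOW = 5000
DEFAULT_STEP = 500
DEFAULT_MIN_SNPS = 10


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n} 1/i**power."""
    return float(sum(1.0 / i**power for i in range(1, n + 1)))


def derived_count_spectrum(matrix: HaplotypeMatrix) -> np.ndarray:
    """Unfolded SFS: counts S_i of sites at derived count i, i = 1..n-1.

    Monomorphic columns are excluded; the returned array has length n-1
    and index 0 holds S_1.
    """
    if not matrix.polarized:
        raise GenomicIOError("derived_count_spectrum requires a polarized matrix")
    n = matrix.n_haplotypes
    if n < 2:
        raise GenomicIOError("need at least 2 haplotypes")
    counts = matrix.allele_counts()
    seg = counts[(counts > 0) & (counts < n)]
    return np.bincount(seg, minlength=n)[1:n]


def _spectrum_from_counts(counts: np.ndarray, n: int) -> np.ndarray:
    seg = counts[(counts > 0) & (counts < n)]
    return np.bincount(seg, minlength=n)[1:n]


def theta_pi(matrix: HaplotypeMatrix) -> float:
    """Mean number of pairwise differences over all haplotype pairs.

    Equals sum_i 2 i (n-i) S_i / (n (n-1)); polarity-free (uses allele
    counts only), so it accepts unpolarized matrices.
    """
    n = matrix.n_haplotypes
    if n < 2:
        raise GenomicIOError("need at least 2 haplotypes")
    counts = matrix.allele_counts().astype(np.float64)
    return float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))


def theta_w(S: int, n: int) -> float:
    """Watterson's estimator S / a1."""
    if n < 2:
        raise GenomicIOError("need at least 2 haplotypes")
    if S == 0:
        return 0.0
    return S / harmonic(n - 1)


def segregating_sites(matrix: HaplotypeMatrix) -> int:
    n = matrix.n_haplotypes
    counts = matrix.allele_counts()
    return int(np.sum((counts > 0) & (counts < n)))


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima (1989)."""
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(matrix: HaplotypeMatrix) -> float:
    """Tajima's D; NaN when S = 0. Folded-safe (never needs polarity)."""
    n = matrix.n_haplotypes
    if n < 2:
        raise GenomicIOError("need at least 2 haplotypes")
    S = segregating_sites(matrix)
    if S == 0:
        return math.nan
    k = tajima_constants(n)
    num = theta_pi(matrix) - theta_w(S, n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return num / math.sqrt(var)


def fay_wu_h(matrix: HaplotypeMatrix) -> tuple[float, float]:
    """(theta_L, H) with theta_L = (1/(n-1)) sum i S_i and H = 2(pi - theta_L)."""
    if not matrix.polarized:
        raise GenomicIOError("fay_wu_h requires a polarized matrix")
    n = matrix.n_haplotypes
    if n < 2:
        raise GenomicIOError("need at least 2 haplotypes")
    spectrum = derived_count_spectrum(matrix)
    i = np.arange(1, n, dtype=np.float64)
    theta_l = float(np.sum(i * spectrum) / (n - 1))
    return theta_l, 2.0 * (theta_pi(matrix) - theta_l)


def theta_h(matrix: HaplotypeMatrix) -> float:
    """Fay-Wu's theta_H = sum 2 i^2 S_i / (n(n-1)); H = pi - theta_H."""
    if not matrix.polarized:
        raise GenomicIOError("theta_h requires a polarized matrix")
    n = matrix.n_haplotypes
    spectrum = derived_count_spectrum(matrix)
    i = np.arange(1, n, dtype=np.float64)
    return float(np.sum(2.0 * i**2 * spectrum) / (n * (n - 1)))


def normalized_dh(matrix: HaplotypeMatrix) -> float:
    """Variance-normalized E = (pi - theta_L) / sqrt(Var), Zeng et al. (2006).

    Var = (n-2)/(6(n-1)) * theta
        + [18 n^2 (3n+2) b_{n+1} - (88 n^3 + 9 n^2 - 13 n + 6)] / (9 n (n-1)^2) * theta2
    with theta = theta_W, theta2 = S(S-1)/(a1^2 + a2), b_{n+1} = sum_{i=1}^{n} 1/i^2.
    Returns NaN when S = 0.
    """
    if not matrix.polarized:
        raise GenomicIOError("normalized_dh requires a polarized matrix")
    n = matrix.n_haplotypes
    S = segregating_sites(matrix)
    if S == 0:
        return math.nan
    a1 = harmonic(n - 1)
    a2 = harmonic(n - 1, power=2)
    bn1 = harmonic(n, power=2)
    theta = theta_w(S, n)
    theta2 = S * (S - 1) / (a1**2 + a2)
    var = (
        (n - 2) / (6.0 * (n - 1)) * theta
        + (18.0 * n**2 * (3 * n + 2) * bn1 - (88.0 * n**3 + 9 * n**2 - 13 * n + 6))
        / (9.0 * n * (n - 1) ** 2)
        * theta2
    )
    theta_l, _ = fay_wu_h(matrix)
    return (theta_pi(matrix) - theta_l) / math.sqrt(var)


@dataclass
class WindowStatRecord:
    """All per-window statistics for one population."""

    region: Region
    population: str
    n_snps: int
    S: int
    pi: float
    pi_per_site: float
    theta_w: float
    theta_w_per_site: float
    tajimas_d: float
    theta_l: float
    H: float
    DH: float
    truncated: bool = False


def _window_record(
    sub: HaplotypeMatrix,
    region: Region,
    population: str,
    min_snps: int,
    truncated: bool,
) -> WindowStatRecord:
    S = segregating_sites(sub)
    pi = theta_pi(sub) if sub.n_sites else 0.0
    tw = theta_w(S, sub.n_haplotypes)
    length = region.length
    if S >= max(min_snps, 1):
        d = tajimas_d(sub)
        if sub.polarized:
            tl, h = fay_wu_h(sub)
            dh = normalized_dh(sub)
        else:
            tl = h = dh = math.nan
    else:
        d = tl = h = dh = math.nan
    return WindowStatRecord(
        region=region,
        population=population,
        n_snps=sub.n_sites,
        S=S,
        pi=pi,
        pi_per_site=pi / length,
        theta_w=tw,
        theta_w_per_site=tw / length,
        tajimas_d=d,
        theta_l=tl,
        H=h,
        DH=dh,
        truncated=truncated,
    )


def sliding_windows(
    region: Region,
    matrix: HaplotypeMatrix,
    population: str = "",
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> list[WindowStatRecord]:
    """Tile ``region`` with windows anchored at its start and compute all stats.

    The final partial window, if any, is emitted with ``truncated=True``.
    Windows with fewer than ``min_snps`` segregating sites report NaN for
    D/H/DH. A region shorter than ``window`` yields a single truncated
    window.
    """
    if step <= 0 or window < step:
        raise GenomicIOError("need window >= step > 0")
    positions = matrix.positions
    records: list[WindowStatRecord] = []
    start = region.start
    while start < region.end:
        end = min(start + window, region.end)
        truncated = end - start < window
        win = Region(region.chrom, start, end, region.label)
        in_win = (positions > start) & (positions <= end)
        sub = matrix.take_sites(np.nonzero(in_win)[0])
        records.append(_window_record(sub, win, population, min_snps, truncated))
        if end >= region.end:
            break
        start += step
    return records


def region_stats(
    region: Region,
    matrix: HaplotypeMatrix,
    population: str = "",
    min_snps: int = 1,
) -> WindowStatRecord:
    """Whole-region statistics as a single (possibly truncated=False) record."""
    sub = matrix.restrict(region)
    return _window_record(sub, region, population, min_snps, truncated=False)


def window_records_to_tsv(records: list[WindowStatRecord], path, header_comment: str = ""):
    """Write per-window TSV (NaN rendered as NA)."""
    def fmt(x: float) -> str:
        return "NA" if isinstance(x, float) and math.isnan(x) else f"{x:.6g}"

    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment + "\n")
        fh.write(
            "chrom\tstart\tend\tpopulation\tn_snps\tS\tpi_per_site\t"
            "theta_w_per_site\ttajimas_d\tH\tDH\ttruncated\n"
        )
        for r in records:
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t{r.population}\t"
                f"{r.n_snps}\t{r.S}\t{fmt(r.pi_per_site)}\t{fmt(r.theta_w_per_site)}\t"
                f"{fmt(r.tajimas_d)}\t{fmt(r.H)}\t{fmt(r.DH)}\t{int(r.truncated)}\n"
            )
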