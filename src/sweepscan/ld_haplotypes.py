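"""Linkage disequilibrium from phased haplotype counts and haplotype reports.

r² is computed directly from joint haplotype frequencies (no EM — inputs
are phased), per population panel, never pooled across populations.
The haplotype-matrix report renders carriers of a focal derived allele
above non-carriers, as in sweep-visualization figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from sweepscan.genomic_io import GenomicIOError, HaplotypeMatrix


@dataclass(frozen=True)
class LdPair:
    id_a: str
    id_b: str
    p_a: float
    p_b: float
    p_ab: float
    D: float
    r2: float

    @property
    def in_phase(self) -> bool:
        """True iff the designated alleles co-occur more than expected (D > 0)."""
        return self.D > 0


def r_squared(matrix: HaplotypeMatrix, site_a: int, site_b: int) -> LdPair:
    """Haplotype-count D and r² between two biallelic sites.

    Allele frequencies refer to the 1-allele at each site (derived when
    the matrix is polarized, ALT otherwise). Raises when either site is
    monomorphic in the selected haplotypes.
    """
    n = matrix.n_haplotypes
    col_a = matrix.data[:, site_a].astype(np.float64)
    col_b = matrix.data[:, site_b].astype(np.float64)
    p_a = col_a.mean()
    p_b = col_b.mean()
    for label, p, idx in (("A", p_a, site_a), ("B", p_b, site_b)):
        if p in (0.0, 1.0):
            raise GenomicIOError(
                f"site {matrix.sites[idx].id} (site_{label.lower()}) is monomorphic"
            )
    p_ab = float(np.mean(col_a * col_b))
    D = p_ab - p_a * p_b
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LdPair(
        id_a=matrix.sites[site_a].id,
        id_b=matrix.sites[site_b].id,
        p_a=float(p_a),
        p_b=float(p_b),
        p_ab=p_ab,
        D=float(D),
        r2=float(r2),
    )


def phase_relation(
    matrix: HaplotypeMatrix,
    focal_site: int,
    focal_allele: int,
    partner_site: int,
    partner_allele: int,
) -> bool:
    """True iff the specified allele pair co-occurs more than expected.

    D for the designated allele pair must be strictly positive; D = 0
    returns False.
    """
    for allele in (focal_allele, partner_allele):
        if allele not in (0, 1):
            raise GenomicIOError("alleles must be 0 or 1")
    a = (matrix.data[:, focal_site] == focal_allele).astype(np.float64)
    b = (matrix.data[:, partner_site] == partner_allele).astype(np.float64)
    if a.mean() in (0.0, 1.0) or b.mean() in (0.0, 1.0):
        raise GenomicIOError("phase_relation requires both sites polymorphic")
    D = float(np.mean(a * b) - a.mean() * b.mean())
    return D > 0


@dataclass
class HaplotypeReport:
    """Fig-style ordered binary haplotype display around a focal site."""

    site_ids: list[str]
    hap_ids: list[str]
    data: np.ndarray  # reordered rows; 1 = derived
    separator: int  # derived carriers occupy rows [0, separator)
    focal_id: str


def haplotype_matrix_report(
    matrix: HaplotypeMatrix, focal_site: int
) -> HaplotypeReport:
    """Order haplotypes for display: focal-derived carriers on top.

    Within each block rows sort lexicographically; columns are the
    polymorphic sites in positional order. Requires a polarized matrix
    and a polymorphic focal site.
    """
    if not matrix.polarized:
        raise GenomicIOError("haplotype report requires a polarized matrix")
    n = matrix.n_haplotypes
    counts = matrix.allele_counts()
    if counts[focal_site] in (0, n):
        raise GenomicIOError(f"focal site {matrix.sites[focal_site].id} is monomorphic")
    poly = np.nonzero((counts > 0) & (counts < n))[0]
    sub = matrix.data[:, poly]
    derived = matrix.data[:, focal_site] == 1

    def lex_order(rows: np.ndarray) -> np.ndarray:
        # np.lexsort keys are last-significant-first; reverse for left-to-right
        return np.lexsort(rows.T[::-1])

    top = np.nonzero(derived)[0]
    bottom = np.nonzero(~derived)[0]
    order = np.concatenate([top[lex_order(sub[top])], bottom[lex_order(sub[bottom])]])
    return HaplotypeReport(
        site_ids=[matrix.sites[j].id for j in poly],
        hap_ids=[matrix.hap_ids[i] for i in order],
        data=sub[order].copy(),
        separator=int(derived.sum()),
        focal_id=matrix.sites[focal_site].id,
    )


def render_text(report: HaplotypeReport, derived_char: str = "#", ancestral_char: str = ".") -> str:
    """Text-art rendering; a dashed line separates derived from ancestral carriers."""
    width = report.data.shape[1]
    lines = [f"focal={report.focal_id} (derived carriers above the line)"]
    for i, row in enumerate(report.data):
        if i == report.separator:
            lines.append("-" * width)
        lines.append("".join(derived_char if x else ancestral_char for x in row))
    if report.separator == len(report.data):
        lines.append("-" * width)
    return "\n".join(lines) + "\n"


def parse_text(text: str) -> tuple[np.ndarray, int]:
    """Inverse of :func:`render_text`: (matrix, separator index)."""
    lines = [ln for ln in text.splitlines() if ln]
    rows: list[list[int]] = []
    separator = None
    for ln in lines[1:]:
        if set(ln) == {"-"}:
            separator = len(rows)
            continue
        rows.append([1 if ch == "#" else 0 for ch in ln])
    if separator is None:
        raise GenomicIOError("no separator line in haplotype report text")
    return np.array(rows, dtype=np.uint8), separator


def render_image(report: HaplotypeReport, path) -> None:
    """PNG/SVG rendering: dark = derived, light = ancestral."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_hap, n_site = report.data.shape
    fig, ax = plt.subplots(figsize=(max(3, n_site * 0.12), max(2, n_hap * 0.12)))
    ax.imshow(1 - report.data, cmap="gray", aspect="auto", interpolation="nearest",
              vmin=-0.3, vmax=1.0)
    ax.axhline(report.separator - 0.5, color="black", linewidth=2)
    ax.set_xlabel("polymorphic sites")
    ax.set_ylabel("haplotypes")
    ax.set_title(f"focal {report.focal_id}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ld_pairs_to_tsv(pairs, population: str, path, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment + "\n")
        fh.write("idA\tidB\tpopulation\tpA\tpB\tpAB\tD\tr2\n")
        for p in pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{population}\t{p.p_a:.6g}\t{p.p_b:.6g}\t"
                f"{p.p_ab:.6g}\t{p.D:.6g}\t{p.r2:.6g}\n"
            )
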