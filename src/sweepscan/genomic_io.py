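"""Standard-format I/O and ancestral-allele polarization.

Reads phased VCF regions into haplotype matrices, parses panel TSVs and
BED region files, resolves ancestral alleles (explicit table > VCF ``AA``
INFO tag > outgroup parsimony) and polarizes matrices so that allele 1
means "derived".

Coordinate convention: VCF positions are 1-based as in the source file;
:class:`Region` arithmetic is 0-based half-open. Conversion happens only
at the I/O boundary.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")


class GenomicIOError(ValueError):
    """Raised on malformed inputs or contract violations at the I/O boundary."""


@dataclass(frozen=True)
class Region:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise GenomicIOError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def flanked(self, flank: int) -> "Region":
        """Region extended by ``flank`` bp on each side, clipped at 0."""
        return replace(self, start=max(0, self.start - flank), end=self.end + flank)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        return chrom == self.chrom and self.start < pos_1based <= self.end


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV; ``pos`` is 1-based as in the source VCF.

    ``ancestral`` is one of ``"ref"``, ``"alt"`` or ``"unresolved"``.
    """

    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    ancestral: str = "unresolved"

    def __post_init__(self) -> None:
        if self.ancestral not in ("ref", "alt", "unresolved"):
            raise GenomicIOError(f"bad ancestral designation {self.ancestral!r}")

    @property
    def ancestral_allele(self) -> str | None:
        if self.ancestral == "ref":
            return self.ref_allele
        if self.ancestral == "alt":
            return self.alt_allele
        return None

    @property
    def derived_allele(self) -> str | None:
        if self.ancestral == "ref":
            return self.alt_allele
        if self.ancestral == "alt":
            return self.ref_allele
        return None


class PopulationPanel:
    """Mapping sample -> population label; populations partition the samples."""

    def __init__(self, sample_to_pop: Mapping[str, str]):
        self._map = dict(sample_to_pop)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PopulationPanel":
        """Read a panel TSV with header ``sample<TAB>population``."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sample", "population"]:
                raise GenomicIOError(
                    f"panel {path}: expected header 'sample\\tpopulation', got {header!r}"
                )
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise GenomicIOError(f"panel {path}: malformed line {line!r}")
                sample, pop = fields[0], fields[1]
                if sample in mapping:
                    raise GenomicIOError(f"panel {path}: duplicate sample {sample}")
                mapping[sample] = pop
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tpopulation\n")
            for sample, pop in self._map.items():
                fh.write(f"{sample}\t{pop}\n")

    def population_of(self, sample: str) -> str:
        try:
            return self._map[sample]
        except KeyError:
            raise GenomicIOError(f"sample {sample!r} not present in panel") from None

    def samples(self, populations: Iterable[str] | None = None) -> list[str]:
        if populations is None:
            return list(self._map)
        wanted = set(populations)
        unknown = wanted - set(self._map.values())
        if unknown:
            raise GenomicIOError(f"unknown population label(s): {sorted(unknown)}")
        return [s for s, p in self._map.items() if p in wanted]

    @property
    def populations(self) -> list[str]:
        return sorted(set(self._map.values()))

    def __contains__(self, sample: str) -> bool:
        return sample in self._map

    def __len__(self) -> int:
        return len(self._map)


@dataclass
class HaplotypeMatrix:
    """Phased 0/1 allele matrix, haplotypes x ordered variant sites.

    When ``polarized`` is False, 1 encodes the VCF ALT allele; when True,
    1 encodes the derived allele. ``exclusions`` counts sites dropped
    during loading/polarization by reason.
    """

    sites: list[VariantSite]
    hap_ids: list[str]
    data: np.ndarray
    polarized: bool = False
    exclusions: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise GenomicIOError("haplotype data must be 2-D")
        if self.data.shape != (len(self.hap_ids), len(self.sites)):
            raise GenomicIOError(
                f"shape {self.data.shape} != ({len(self.hap_ids)} haplotypes, "
                f"{len(self.sites)} sites)"
            )
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise GenomicIOError("haplotype entries must be 0/1")
        for prev, cur in zip(self.sites, self.sites[1:]):
            if prev.chrom == cur.chrom and prev.pos >= cur.pos:
                raise GenomicIOError(
                    "site positions must be strictly increasing within a chromosome"
                )

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def allele_counts(self) -> np.ndarray:
        """Per-site count of the 1-allele."""
        return self.data.sum(axis=0).astype(np.int64)

    def derived_freqs(self) -> np.ndarray:
        """Per-site DAF; requires a polarized matrix."""
        if not self.polarized:
            raise GenomicIOError("derived frequencies require a polarized matrix")
        return self.allele_counts() / self.n_haplotypes

    def alt_freqs(self) -> np.ndarray:
        return self.allele_counts() / self.n_haplotypes

    def minor_freqs(self) -> np.ndarray:
        f = self.allele_counts() / self.n_haplotypes
        return np.minimum(f, 1.0 - f)

    def take_sites(self, idx: Sequence[int] | np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        return HaplotypeMatrix(
            sites=[self.sites[i] for i in idx],
            hap_ids=list(self.hap_ids),
            data=self.data[:, idx],
            polarized=self.polarized,
            exclusions=Counter(self.exclusions),
        )

    def take_haplotypes(self, idx: Sequence[int] | np.ndarray) -> "HaplotypeMatrix":
        idx = np.asarray(idx, dtype=np.int64)
        return HaplotypeMatrix(
            sites=list(self.sites),
            hap_ids=[self.hap_ids[i] for i in idx],
            data=self.data[idx, :],
            polarized=self.polarized,
            exclusions=Counter(self.exclusions),
        )

    def restrict(self, region: Region) -> "HaplotypeMatrix":
        keep = [
            j for j, s in enumerate(self.sites) if region.contains(s.chrom, s.pos)
        ]
        return self.take_sites(keep)


def _phased_alleles(gt: Sequence[int | bool]) -> tuple[int, int] | None:
    """cyvcf2 genotype row -> (a, b) or None if missing/unphased."""
    if len(gt) < 3:
        return None
    a, b, phased = gt[0], gt[1], gt[-1]
    if a < 0 or b < 0 or not phased:
        return None
    return int(a), int(b)


def read_phased_vcf(
    path: str | Path,
    region: Region | None,
    panel: PopulationPanel,
    populations: Iterable[str] | None = None,
) -> HaplotypeMatrix:
    """Load phased biallelic SNVs in ``region`` for the requested populations.

    ``region=None`` loads the whole file (callers then restrict per
    region, which avoids re-streaming the VCF for every locus).

    Multiallelic sites, indels, and sites with any missing or unphased
    genotype among the selected samples are excluded; exclusion counts
    are recorded on the returned matrix and logged. The VCF ``AA`` INFO
    tag, when present and matching REF or ALT, pre-fills the ancestral
    designation of each site.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    for s in vcf_samples:
        if s not in panel and populations is None:
            raise GenomicIOError(f"VCF sample {s!r} missing from panel")
    wanted = set(panel.samples(populations))
    sample_idx = [i for i, s in enumerate(vcf_samples) if s in wanted]
    missing = wanted - set(vcf_samples)
    if missing:
        raise GenomicIOError(f"panel sample(s) absent from VCF: {sorted(missing)}")
    selected = [vcf_samples[i] for i in sample_idx]

    hap_ids = [f"{s}_{k}" for s in selected for k in (0, 1)]
    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    exclusions: Counter = Counter()

    for rec in vcf:
        if region is not None and not region.contains(rec.CHROM, rec.POS):
            continue
        if len(rec.ALT) != 1:
            exclusions["multiallelic"] += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            exclusions["not_snv"] += 1
            continue
        gts = rec.genotypes
        col = np.empty(2 * len(sample_idx), dtype=np.uint8)
        ok = True
        for k, i in enumerate(sample_idx):
            pair = _phased_alleles(gts[i])
            if pair is None:
                ok = False
                break
            col[2 * k] = pair[0]
            col[2 * k + 1] = pair[1]
        if not ok:
            exclusions["missing_or_unphased"] += 1
            logger.warning(
                "dropping site %s:%d (%s): missing or unphased genotype",
                rec.CHROM, rec.POS, rec.ID or ".",
            )
            continue
        aa = rec.INFO.get("AA")
        ancestral = "unresolved"
        if isinstance(aa, str):
            aa = aa.split("|")[0].upper()
            if aa == ref:
                ancestral = "ref"
            elif aa == alt:
                ancestral = "alt"
        sites.append(
            VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref_allele=ref,
                alt_allele=alt,
                ancestral=ancestral,
            )
        )
        columns.append(col)

    data = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(hap_ids), 0), dtype=np.uint8)
    )
    for reason, n in exclusions.items():
        logger.info("read_phased_vcf %s: excluded %d site(s): %s", path, n, reason)
    return HaplotypeMatrix(
        sites=sites, hap_ids=hap_ids, data=data, polarized=False, exclusions=exclusions
    )


def parsimony_ancestral(
    outgroup_alleles: Sequence[str | None], ingroup_alleles: tuple[str, str]
) -> str:
    """Majority-rule parsimony ancestral call from outgroup observations.

    Returns ``"ref"``/``"alt"`` naming the ingroup allele matched by a
    strict majority of non-missing outgroup alleles, else ``"unresolved"``
    (tie, all missing, or majority allele matches neither ingroup allele).
    Total function: never raises on data content.
    """
    observed = [a.upper() for a in outgroup_alleles if a and a != "." and a != "-"]
    if not observed:
        return "unresolved"
    counts = Counter(observed)
    top, top_n = counts.most_common(1)[0]
    if sum(1 for c in counts.values() if c == top_n) > 1:
        return "unresolved"
    ref, alt = ingroup_alleles
    if top == ref:
        return "ref"
    if top == alt:
        return "alt"
    return "unresolved"


AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


def polarize(
    matrix: HaplotypeMatrix,
    ancestral_table: Mapping[tuple[str, int], str] | None = None,
    outgroup_columns: Mapping[tuple[str, int], Sequence[str | None]] | None = None,
    drop_strand_ambiguous_mismatches: bool = True,
) -> HaplotypeMatrix:
    """Polarize a matrix so that allele 1 means "derived".

    Ancestral source precedence: explicit ``ancestral_table`` (chrom, pos)
    -> allele, then the per-site designation already loaded (VCF ``AA``
    tag), then parsimony over ``outgroup_columns``. Sites that remain
    unresolved, or whose tabled ancestral allele matches neither REF nor
    ALT, are dropped with a warning and counted.
    """
    if matrix.polarized:
        return matrix
    keep: list[int] = []
    new_sites: list[VariantSite] = []
    flip: list[bool] = []
    exclusions = Counter(matrix.exclusions)
    for j, site in enumerate(matrix.sites):
        designation = site.ancestral
        key = (site.chrom, site.pos)
        if ancestral_table is not None and key in ancestral_table:
            aa = ancestral_table[key].upper()
            if aa == site.ref_allele:
                designation = "ref"
            elif aa == site.alt_allele:
                designation = "alt"
            else:
                ingroup = {site.ref_allele, site.alt_allele}
                if drop_strand_ambiguous_mismatches and any(
                    ingroup == pair for pair in AMBIGUOUS_PAIRS
                ):
                    logger.warning(
                        "site %s:%d: ancestral %s on A/T or C/G site, possible strand "
                        "issue; dropped", site.chrom, site.pos, aa,
                    )
                    exclusions["strand_ambiguous"] += 1
                    continue
                logger.warning(
                    "site %s:%d: ancestral allele %s matches neither %s nor %s; dropped",
                    site.chrom, site.pos, aa, site.ref_allele, site.alt_allele,
                )
                exclusions["ancestral_mismatch"] += 1
                continue
        elif designation == "unresolved" and outgroup_columns is not None:
            designation = parsimony_ancestral(
                outgroup_columns.get(key, ()), (site.ref_allele, site.alt_allele)
            )
        if designation == "unresolved":
            exclusions["unresolved_ancestral"] += 1
            continue
        keep.append(j)
        new_sites.append(replace(site, ancestral=designation))
        flip.append(designation == "alt")

    data = matrix.data[:, keep].copy()
    flip_arr = np.array(flip, dtype=bool)
    if flip_arr.any():
        data[:, flip_arr] = 1 - data[:, flip_arr]
    dropped = len(matrix.sites) - len(keep)
    if dropped:
        logger.info("polarize: dropped %d of %d sites", dropped, len(matrix.sites))
    return HaplotypeMatrix(
        sites=new_sites,
        hap_ids=list(matrix.hap_ids),
        data=data,
        polarized=True,
        exclusions=exclusions,
    )


def read_bed(path: str | Path) -> list[Region]:
    """Read a BED file (0-based half-open) into labelled regions."""
    regions: list[Region] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise GenomicIOError(f"BED {path}: malformed line {line!r}")
            label = fields[3] if len(fields) > 3 else f"{fields[0]}:{fields[1]}-{fields[2]}"
            regions.append(Region(fields[0], int(fields[1]), int(fields[2]), label))
    return regions


def write_bed(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def tsv_header_comment(tool: str, **params) -> str:
    """Commented provenance line for output TSVs."""
    from sweepscan import __version__

    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# sweepscan {__version__} {tool} {kv}".rstrip()
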