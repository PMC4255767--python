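"""Coalescent generator of phased, polarized synthetic SNP cohorts.

Hand-written Hudson-style simulator (infinite sites, no intra-locus
recombination) with three scenarios:

* ``neutral`` — Kingman coalescent at equilibrium;
* ``island`` — two demes, symmetric scaled migration (structured
  coalescent; coalescence only within demes);
* ``sweep`` — hard-sweep approximation: a chosen fraction of haplotypes
  carries a focal derived allele whose intra-allelic genealogy has its
  coalescent times multiplied by a compression factor c (c -> 0 gives a
  star genealogy, i.e. iPi_D -> 0); the rest of the genealogy is
  neutral. Optionally a second, neutral deme is attached through the
  island structured coalescent so that the sweep locus also shows
  allele-frequency differentiation.

Time is in units of 2N generations; mutations are Poisson with rate
theta/2 per unit branch length (theta = 4*N*mu per locus), so
E[S] = theta * a1 and E[pi] = theta. Each locus gets its own generator
seeded from (master seed, locus index) for independent reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from sweepscan.genomic_io import (
    GenomicIOError,
    HaplotypeMatrix,
    PopulationPanel,
    Region,
    VariantSite,
)

_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic scenario."""

    scenario: str = "neutral"  # neutral | island | sweep
    n_haplotypes: int = 20  # per deme for island / two-deme sweep
    theta: float = 5.0  # per locus
    locus_length: int = 70_000
    n_loci: int = 1
    migration: float = 1.0  # 4Nm, island / two-deme sweep
    sweep_daf: float = 0.8
    compression: float = 1.0  # c in (0, 1]
    second_deme: bool = False  # sweep only: attach a neutral deme 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("neutral", "island", "sweep"):
            raise GenomicIOError(f"unknown scenario {self.scenario!r}")
        if self.n_haplotypes < 2 or self.theta < 0 or self.locus_length < 1:
            raise GenomicIOError("invalid simulation parameters")
        if self.scenario == "sweep":
            if not (0.0 < self.sweep_daf < 1.0):
                raise GenomicIOError("sweep_daf must lie in (0, 1)")
            if not (0.0 < self.compression <= 1.0):
                raise GenomicIOError("compression must lie in (0, 1]")
            if round(self.sweep_daf * self.n_haplotypes) < 2:
                raise GenomicIOError("sweep requires >= 2 derived carriers")

    def rng(self, locus_index: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, locus_index])


class _Tree:
    """Growable genealogy: parent/time arrays over leaf + internal nodes."""

    def __init__(self, n_leaves: int):
        self.n_leaves = n_leaves
        self.parent: list[int] = [-1] * n_leaves
        self.time: list[float] = [0.0] * n_leaves

    def new_node(self, t: float) -> int:
        self.parent.append(-1)
        self.time.append(t)
        return len(self.parent) - 1

    def join(self, a: int, b: int, t: float) -> int:
        p = self.new_node(t)
        self.parent[a] = p
        self.parent[b] = p
        return p

    def leaf_sets(self) -> list[np.ndarray]:
        """Descendant-leaf index array per node."""
        n_nodes = len(self.parent)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for v, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(v)
        sets: list[np.ndarray | None] = [None] * n_nodes
        # nodes were created in increasing time order; children precede parents
        for v in range(n_nodes):
            if v < self.n_leaves:
                sets[v] = np.array([v], dtype=np.int64)
            else:
                sets[v] = np.concatenate([sets[c] for c in children[v]])
        return sets  # type: ignore[return-value]

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for roots)."""
        out = np.zeros(len(self.parent))
        for v, p in enumerate(self.parent):
            if p >= 0:
                out[v] = self.time[p] - self.time[v]
        return out


def _coalesce_panmictic(
    tree: _Tree, active: list[int], t: float, rng: np.random.Generator,
    stop_at: float = math.inf,
) -> tuple[list[int], float]:
    """Run pairwise coalescence at rate k(k-1)/2 until one lineage or stop_at."""
    while len(active) > 1:
        k = len(active)
        wait = rng.exponential(2.0 / (k * (k - 1)))
        if t + wait >= stop_at:
            return active, stop_at
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node = tree.join(a, b, t)
        active = [x for idx, x in enumerate(active) if idx not in (i, j)]
        active.append(node)
    return active, t


def _coalesce_island(
    tree: _Tree, active: list[int], demes: list[int], t: float,
    migration: float, rng: np.random.Generator,
    inject: tuple[float, int, int] | None = None,
) -> tuple[list[int], float]:
    """Two-deme structured coalescent with symmetric migration.

    ``inject`` optionally adds (time, node, deme) — a lineage entering
    the process later (the compressed derived-subtree root of a sweep).
    """
    inject_time = inject[0] if inject else math.inf
    while len(active) > 1 or inject is not None:
        counts = [demes.count(0), demes.count(1)]
        coal_rates = [c * (c - 1) / 2.0 for c in counts]
        mig_rate = len(active) * migration / 2.0
        total = sum(coal_rates) + mig_rate
        if total == 0.0:
            if inject is not None:
                t = inject_time
                active.append(inject[1])
                demes.append(inject[2])
                inject = None
                inject_time = math.inf
                continue
            raise GenomicIOError(
                "no possible event: migration = 0 with lineages in both demes"
            )
        wait = rng.exponential(1.0 / total)
        if t + wait >= inject_time:
            t = inject_time
            active.append(inject[1])  # type: ignore[index]
            demes.append(inject[2])  # type: ignore[index]
            inject = None
            inject_time = math.inf
            continue
        t += wait
        u = rng.random() * total
        if u < mig_rate:
            i = int(rng.integers(len(active)))
            demes[i] = 1 - demes[i]
            continue
        u -= mig_rate
        deme = 0 if u < coal_rates[0] else 1
        members = [i for i, d in enumerate(demes) if d == deme]
        i, j = rng.choice(len(members), size=2, replace=False)
        ii, jj = members[i], members[j]
        node = tree.join(active[ii], active[jj], t)
        active = [x for idx, x in enumerate(active) if idx not in (ii, jj)]
        demes = [d for idx, d in enumerate(demes) if idx not in (ii, jj)]
        active.append(node)
        demes.append(deme)
    return active, t


def _place_mutations(
    tree: _Tree,
    theta: float,
    locus_length: int,
    rng: np.random.Generator,
    chrom: str,
    forced: list[tuple[int, int]] | None = None,
) -> tuple[list[VariantSite], np.ndarray, dict[int, int]]:
    """Poisson mutations on branches -> (sites, data columns, forced index map).

    ``forced`` entries (node, position) add a guaranteed mutation on the
    branch above ``node`` at ``position``; the returned map gives their
    column indices in the final matrix.
    """
    n = tree.n_leaves
    lengths = tree.branch_lengths()
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total) if total > 0 else 0
    branch_of = (
        rng.choice(len(lengths), size=n_mut, p=lengths / total) if n_mut else
        np.empty(0, dtype=np.int64)
    )
    forced = forced or []
    n_total = n_mut + len(forced)
    if n_total == 0:
        return [], np.zeros((n, 0), dtype=np.uint8), {}
    if n_total > locus_length:
        raise GenomicIOError("more mutations than available positions; raise locus_length")

    forced_pos = {pos for _, pos in forced}
    free = rng.choice(locus_length, size=min(n_total, locus_length), replace=False) + 1
    positions: list[int] = []
    used = set(forced_pos)
    fi = iter(free)
    while len(positions) < n_mut:
        p = int(next(fi))
        if p in used:
            continue
        used.add(p)
        positions.append(p)

    entries: list[tuple[int, int, bool]] = [
        (positions[m], int(branch_of[m]), False) for m in range(n_mut)
    ]
    entries += [(pos, node, True) for node, pos in forced]
    entries.sort()

    sets = tree.leaf_sets()
    sites: list[VariantSite] = []
    cols = np.zeros((n, len(entries)), dtype=np.uint8)
    forced_idx: dict[int, int] = {}
    for j, (pos, node, is_forced) in enumerate(entries):
        ref, alt = _PAIRS[int(rng.integers(len(_PAIRS)))]
        cols[sets[node], j] = 1
        sites.append(
            VariantSite(
                chrom=chrom, pos=pos, id=f"{chrom}_{pos}",
                ref_allele=ref, alt_allele=alt, ancestral="ref",
            )
        )
        if is_forced:
            forced_idx[node] = j
    return sites, cols, forced_idx


def _hap_ids(n: int, prefix: str = "s") -> list[str]:
    return [f"{prefix}{i // 2:04d}_{i % 2}" for i in range(n)]


def simulate_neutral(
    config: SimulationConfig, locus_index: int = 0, chrom: str | None = None
) -> HaplotypeMatrix:
    """One neutral-equilibrium locus; returned matrix is polarized (1 = derived)."""
    rng = config.rng(locus_index)
    n = config.n_haplotypes
    tree = _Tree(n)
    active, _ = _coalesce_panmictic(tree, list(range(n)), 0.0, rng)
    chrom = chrom or f"L{locus_index:06d}"
    sites, cols, _ = _place_mutations(tree, config.theta, config.locus_length, rng, chrom)
    return HaplotypeMatrix(
        sites=sites, hap_ids=_hap_ids(n), data=cols, polarized=True
    )


def simulate_island(
    config: SimulationConfig, locus_index: int = 0, chrom: str | None = None
) -> tuple[HaplotypeMatrix, list[str]]:
    """Two-deme island locus; returns (matrix, deme label per haplotype).

    ``n_haplotypes`` is the per-deme sample size; deme labels are
    ``pop1``/``pop2``.
    """
    if config.migration <= 0:
        raise GenomicIOError("island model needs migration > 0")
    rng = config.rng(locus_index)
    n_per = config.n_haplotypes
    n = 2 * n_per
    tree = _Tree(n)
    demes = [0] * n_per + [1] * n_per
    _coalesce_island(tree, list(range(n)), list(demes), 0.0, config.migration, rng)
    chrom = chrom or f"L{locus_index:06d}"
    sites, cols, _ = _place_mutations(tree, config.theta, config.locus_length, rng, chrom)
    labels = ["pop1"] * n_per + ["pop2"] * n_per
    matrix = HaplotypeMatrix(sites=sites, hap_ids=_hap_ids(n), data=cols, polarized=True)
    return matrix, labels


def simulate_sweep(
    config: SimulationConfig, locus_index: int = 0, chrom: str | None = None
) -> tuple[HaplotypeMatrix, int, list[str]]:
    """Hard-sweep approximation; returns (matrix, focal site index, deme labels).

    round(sweep_daf * n) haplotypes carry the focal derived allele; the
    derived-carrier subtree's internal times are multiplied by the
    compression factor before mutation placement, and its root rejoins
    the (neutral or two-deme) remainder of the genealogy. With
    ``second_deme`` the sweep sits in deme 1 and a neutral deme 2 of the
    same size is coupled through migration.
    """
    rng = config.rng(locus_index)
    n1 = config.n_haplotypes
    nd = int(round(config.sweep_daf * n1))
    n = n1 + (n1 if config.second_deme else 0)
    tree = _Tree(n)

    derived_leaves = list(range(nd))  # deme-1 leaves carrying the derived allele
    sub_active, t_droot = _coalesce_panmictic(tree, list(derived_leaves), 0.0, rng)
    droot = sub_active[0]
    # compress the intra-allelic genealogy: scale times of its internal nodes
    if config.compression < 1.0:
        for v in range(tree.n_leaves, len(tree.time)):
            tree.time[v] *= config.compression
        t_droot *= config.compression

    ancestral_leaves = list(range(nd, n))
    if config.second_deme:
        demes = [0] * (n1 - nd) + [1] * n1
        _coalesce_island(
            tree, list(ancestral_leaves), demes, 0.0, config.migration, rng,
            inject=(t_droot, droot, 0),
        )
    else:
        active = list(ancestral_leaves)
        active, t = _coalesce_panmictic(tree, active, 0.0, rng, stop_at=t_droot)
        active.append(droot)
        # the derived root enters at t_droot even if the ancestral class
        # coalesced earlier
        _coalesce_panmictic(tree, active, max(t, t_droot), rng)

    chrom = chrom or f"L{locus_index:06d}"
    focal_pos = config.locus_length // 2
    sites, cols, forced_idx = _place_mutations(
        tree, config.theta, config.locus_length, rng, chrom,
        forced=[(droot, focal_pos)],
    )
    focal_index = forced_idx[droot]
    labels = ["pop1"] * n1 + (["pop2"] * n1 if config.second_deme else [])
    matrix = HaplotypeMatrix(sites=sites, hap_ids=_hap_ids(n), data=cols, polarized=True)
    return matrix, focal_index, labels


@dataclass
class CohortLocus:
    """One simulated locus with its provenance, ready for cohort writing."""

    matrix: HaplotypeMatrix
    config: SimulationConfig
    role: str  # control | test
    focal_index: int | None = None
    deme_labels: list[str] = field(default_factory=list)


def simulate_locus(
    config: SimulationConfig, locus_index: int, role: str = "control"
) -> CohortLocus:
    chrom = f"L{locus_index:06d}"
    if config.scenario == "neutral":
        m = simulate_neutral(config, locus_index, chrom)
        return CohortLocus(m, config, role, None, ["pop1"] * m.n_haplotypes)
    if config.scenario == "island":
        m, labels = simulate_island(config, locus_index, chrom)
        return CohortLocus(m, config, role, None, labels)
    m, focal, labels = simulate_sweep(config, locus_index, chrom)
    return CohortLocus(m, config, role, focal, labels)


def build_two_deme_cohort(
    out_dir: str | Path,
    n_controls: int = 200,
    n_neutral_tests: int = 10,
    include_sweep: bool = True,
    n_haplotypes: int = 40,
    theta: float = 30.0,
    locus_length: int = 70_000,
    migration: float = 2.0,
    compression: float = 0.02,
    sweep_daf: float = 0.8,
    structure: str = "island",
    seed: int = 0,
) -> dict[str, Path]:
    """Assemble a two-population scan cohort with an optional planted sweep.

    ``structure="island"`` draws control and neutral test loci from the
    two-deme island model; ``structure="panmictic"`` draws them from one
    panmictic deme and labels the two halves as pseudo-populations
    (F_ST is then pure assignment noise, the cleanest null for the
    combined caller). The planted sweep locus always carries its focal
    derived allele in pop1. Also writes ``control_regions.bed`` /
    ``test_regions.bed`` splits so the cohort plugs straight into a scan
    config.
    """
    if structure == "island":
        neutral_cfg = SimulationConfig(
            scenario="island", n_haplotypes=n_haplotypes, theta=theta,
            locus_length=locus_length, migration=migration, seed=seed,
        )
    elif structure == "panmictic":
        neutral_cfg = SimulationConfig(
            scenario="neutral", n_haplotypes=2 * n_haplotypes, theta=theta,
            locus_length=locus_length, seed=seed,
        )
    else:
        raise GenomicIOError(f"unknown cohort structure {structure!r}")

    def neutral_locus(idx: int, role: str) -> CohortLocus:
        locus = simulate_locus(neutral_cfg, idx, role=role)
        if structure == "panmictic":
            locus.deme_labels = ["pop1"] * n_haplotypes + ["pop2"] * n_haplotypes
        return locus

    loci: list[CohortLocus] = []
    idx = 0
    for _ in range(n_controls):
        loci.append(neutral_locus(idx, "control"))
        idx += 1
    for _ in range(n_neutral_tests):
        loci.append(neutral_locus(idx, "test"))
        idx += 1
    if include_sweep:
        sweep = SimulationConfig(
            scenario="sweep", n_haplotypes=n_haplotypes, theta=theta,
            locus_length=locus_length, migration=migration,
            compression=compression, sweep_daf=sweep_daf,
            second_deme=True, seed=seed,
        )
        loci.append(simulate_locus(sweep, idx, role="test"))
    paths = write_cohort(loci, out_dir)
    out = Path(out_dir)
    for role in ("control", "test"):
        with open(out / f"{role}_regions.bed", "w") as fh:
            for locus in loci:
                if locus.role == role and locus.matrix.sites:
                    chrom = locus.matrix.sites[0].chrom
                    fh.write(f"{chrom}\t0\t{locus_length}\t{chrom}\n")
        paths[f"{role}_bed"] = out / f"{role}_regions.bed"
    return paths


def write_cohort(loci: Sequence[CohortLocus], out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort as VCF 4.2 (phased GT + AA tag) + panel + BED + truth TSV.

    All loci must share haplotype naming and count (one sample set across
    loci, as in a resequencing panel). Haplotype count must be even
    (diploid VCF). Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    first = loci[0]
    hap_ids = first.matrix.hap_ids
    if any(l.matrix.hap_ids != hap_ids for l in loci):
        raise GenomicIOError("inconsistent sample naming across loci")
    if len(hap_ids) % 2:
        raise GenomicIOError("diploid VCF output needs an even haplotype count")
    samples = [hap_ids[i].rsplit("_", 1)[0] for i in range(0, len(hap_ids), 2)]

    vcf_path = out / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in loci:
            fh.write(
                f"##contig=<ID={locus.matrix.sites[0].chrom if locus.matrix.sites else 'NA'},"
                f"length={locus.config.locus_length}>\n"
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for locus in loci:
            m = locus.matrix
            for j, site in enumerate(m.sites):
                col = m.data[:, j]
                gts = "\t".join(
                    f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(samples))
                )
                fh.write(
                    f"{site.chrom}\t{site.pos}\t{site.id}\t{site.ref_allele}\t"
                    f"{site.alt_allele}\t.\tPASS\tAA={site.ancestral_allele}\tGT\t{gts}\n"
                )

    panel_path = out / "panel.tsv"
    for i in range(len(samples)):
        if first.deme_labels[2 * i] != first.deme_labels[2 * i + 1]:
            raise GenomicIOError(
                "sample straddles demes; use an even per-deme haplotype count"
            )
    pops = {samples[i]: first.deme_labels[2 * i] for i in range(len(samples))}
    PopulationPanel(pops).to_tsv(panel_path)

    bed_path = out / "loci.bed"
    with open(bed_path, "w") as fh:
        for locus in loci:
            chrom = locus.matrix.sites[0].chrom if locus.matrix.sites else "NA"
            fh.write(f"{chrom}\t0\t{locus.config.locus_length}\t{locus.role}\n")

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "chrom\trole\tscenario\ttheta\tn_haplotypes\tmigration\tsweep_daf\t"
            "compression\tfocal_id\tfocal_pos\n"
        )
        for locus in loci:
            chrom = locus.matrix.sites[0].chrom if locus.matrix.sites else "NA"
            c = locus.config
            if locus.focal_index is not None:
                fs = locus.matrix.sites[locus.focal_index]
                focal_id, focal_pos = fs.id, str(fs.pos)
            else:
                focal_id, focal_pos = "NA", "NA"
            fh.write(
                f"{chrom}\t{locus.role}\t{c.scenario}\t{c.theta}\t{c.n_haplotypes}\t"
                f"{c.migration}\t{c.sweep_daf}\t{c.compression}\t{focal_id}\t{focal_pos}\n"
            )
    return {"vcf": vcf_path, "panel": panel_path, "bed": bed_path, "truth": truth_path}
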