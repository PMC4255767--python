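"""Stochastic validation experiments for the scan machinery.

Each function runs a self-contained simulation study (fixed seed in,
measured quantities out) used by the acceptance suite: neutral-coalescent
expectations, empirical-calibration uniformity, island-model F_ST
behaviour, DIND sweep power, and end-to-end sweep recovery through the
full pipeline. Scales are chosen to fit a single CPU in minutes.
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sweepscan import dind_test as dt
from sweepscan import empirical_calibration as cal
from sweepscan import fst_differentiation as fst
from sweepscan import sfs_stats as sfs
from sweepscan import synthetic_data as syn


def neutral_expectations(
    seed: int, n: int = 20, theta: float = 5.0, reps: int = 2000
) -> dict[str, float]:
    """Mean S, pi, Tajima's D and DH over neutral replicates.

    Neutral theory gives E[S] = theta*a1, E[pi] = theta, and D and DH
    centred near 0.
    """
    cfg = syn.SimulationConfig(n_haplotypes=n, theta=theta, seed=seed)
    S, pis, Ds, DHs = [], [], [], []
    for i in range(reps):
        m = syn.simulate_neutral(cfg, i)
        S.append(m.n_sites)
        pis.append(sfs.theta_pi(m))
        d = sfs.tajimas_d(m)
        dh = sfs.normalized_dh(m)
        if not math.isnan(d):
            Ds.append(d)
        if not math.isnan(dh):
            DHs.append(dh)
    return {
        "mean_S": float(np.mean(S)),
        "expected_S": theta * sfs.harmonic(n - 1),
        "mean_pi": float(np.mean(pis)),
        "expected_pi": theta,
        "mean_D": float(np.mean(Ds)),
        "mean_DH": float(np.mean(DHs)),
    }


def fst_calibration_uniformity(
    seed: int,
    n1: int = 90,
    n2: int = 110,
    theta: float = 20.0,
    n_controls: int = 3000,
    n_tests: int = 500,
    min_bin_count: int = cal.DEFAULT_MIN_BIN_COUNT,
) -> dict[str, float]:
    """Fraction of neutral test variants at F_ST rank >= 0.95.

    Two panmictic pseudo-populations are cut from single-deme neutral
    loci. Unequal sizes are deliberate: with n1 = n2 the estimator is
    symmetric in the pseudo-population labels, which doubles the tie
    atoms of its discrete support and (under the ties-count-below rank
    rule) pins the exceedance fraction well below the nominal 5%.
    """
    n = n1 + n2
    cfg = syn.SimulationConfig(n_haplotypes=n, theta=theta, seed=seed)

    def records(lo: int, hi: int) -> list[fst.FstRecord]:
        out = []
        for i in range(lo, hi):
            m = syn.simulate_neutral(cfg, i)
            a = m.take_haplotypes(range(n1))
            b = m.take_haplotypes(range(n1, n))
            out.extend(fst.fst_records(a, b, ("popA", "popB")))
        return out

    null = cal.build_null(
        records(0, n_controls), "fst", ("MAF", fst.N_MAF_CLASSES),
        min_bin_count=min_bin_count,
    )
    hits = total = 0
    for rec in records(n_controls, n_controls + n_tests):
        rank = null.rank(rec.fst, rec.maf_bin)
        if math.isnan(rank):
            continue
        total += 1
        hits += rank >= 0.95
    return {"exceedance": hits / total, "n_ranked": total}


@dataclass
class DindCalibration:
    exceedance: float
    n_ranked: int
    null: cal.EmpiricalNull
    batch_max: float


def dind_calibration_uniformity(
    seed: int,
    n: int = 40,
    theta: float = 30.0,
    n_controls: int = 3000,
    n_tests: int = 300,
    min_bin_count: int = cal.DEFAULT_MIN_BIN_COUNT,
) -> DindCalibration:
    """Fraction of neutral test variants at DIND rank >= 0.95
    (calibrated DAF bins only); returns the null for reuse in power
    studies at matched parameters."""
    cfg = syn.SimulationConfig(n_haplotypes=n, theta=theta, seed=seed)

    def records(lo: int, hi: int) -> list[dt.DindRecord]:
        out = []
        for i in range(lo, hi):
            out.extend(dt.dind_records(syn.simulate_neutral(cfg, i), "pop"))
        return out

    ctrl = records(0, n_controls)
    test = records(n_controls, n_controls + n_tests)
    dt.resolve_sentinels(ctrl + test)  # batch-global, control + test together
    null = cal.build_null(ctrl, "dind", ("DAF", dt.N_DAF_CLASSES),
                          min_bin_count=min_bin_count)
    dt.dind_scan(test, null)
    ranked = [r for r in test if not math.isnan(r.rank)]
    hits = sum(r.rank >= 0.95 for r in ranked)
    finite = [r.dind for r in ctrl + test if not r.skip_reason and not math.isnan(r.dind)]
    return DindCalibration(
        exceedance=hits / len(ranked),
        n_ranked=len(ranked),
        null=null,
        batch_max=max(finite),
    )


def dind_sweep_power(
    seed: int,
    null: cal.EmpiricalNull,
    batch_max: float,
    compressions: tuple[float, ...] = (0.2, 0.1, 0.05),
    n: int = 40,
    theta: float = 30.0,
    sweep_daf: float = 0.8,
    reps: int = 150,
) -> dict[float, float]:
    """Proportion of sweep focal variants reaching DIND rank >= 0.95,
    per compression factor, against a neutral null at matched n/theta.

    Sweep sentinels are resolved with the neutral batch maximum so test
    and control sentinel policies coincide.
    """
    bad_bins = dt.uncalibrated_bins(null)
    power: dict[float, float] = {}
    for c in compressions:
        cfg = syn.SimulationConfig(
            scenario="sweep", n_haplotypes=n, theta=theta, compression=c,
            sweep_daf=sweep_daf, seed=seed + int(1000 * c),
        )
        hits = total = 0
        for i in range(reps):
            m, focal, _ = syn.simulate_sweep(cfg, i)
            try:
                _, _, dind, sentinel = dt.dind_statistic(m, focal)
            except Exception:
                continue
            if sentinel:
                dind = batch_max + dt.SENTINEL_OFFSET
            daf = float(m.derived_freqs()[focal])
            b = dt.daf_bin(daf)
            if b in bad_bins:
                continue
            rank = null.rank(dind, b)
            if math.isnan(rank):
                continue
            total += 1
            hits += rank >= 0.95
        power[c] = hits / total if total else math.nan
    return power


def island_fst_curve(
    seed: int,
    migrations: tuple[float, ...] = (0.5, 2.0, 8.0, 100.0),
    n: int = 20,
    theta: float = 5.0,
    reps: int = 300,
) -> dict[float, float]:
    """Mean per-SNP Weir-Cockerham F_ST per scaled migration rate."""
    out: dict[float, float] = {}
    for mig in migrations:
        cfg = syn.SimulationConfig(
            scenario="island", n_haplotypes=n, theta=theta, migration=mig, seed=seed
        )
        values: list[float] = []
        for i in range(reps):
            m, _ = syn.simulate_island(cfg, i)
            c1 = m.data[:n].sum(axis=0)
            c2 = m.data[n:].sum(axis=0)
            for j in range(m.n_sites):
                v = fst.wc_fst(n, c1[j] / n, n, c2[j] / n)
                if not math.isnan(v):
                    values.append(v)
        out[mig] = float(np.mean(values))
    return out


def sweep_recovery_scan(
    seed: int,
    n_controls: int = 600,
    n_neutral_tests: int = 100,
    n_haplotypes: int = 16,
    theta: float = 30.0,
    compression: float = 0.02,
    sweep_daf: float = 0.8,
    out_dir: str | Path | None = None,
) -> dict[str, float | bool]:
    """End-to-end pipeline run on a panmictic cohort with one planted sweep.

    Returns whether the sweep locus was called and the false-call
    fraction among the neutral test loci.
    """
    from sweepscan.pipeline_cli import ScanConfig, run_scan

    work = Path(out_dir) if out_dir else Path(tempfile.mkdtemp(prefix="sweepscan_"))
    paths = syn.build_two_deme_cohort(
        work / "cohort", n_controls=n_controls, n_neutral_tests=n_neutral_tests,
        include_sweep=True, n_haplotypes=n_haplotypes, theta=theta,
        migration=50.0, compression=compression, sweep_daf=sweep_daf,
        structure="panmictic", seed=seed,
    )
    cfg = ScanConfig(
        vcf=str(paths["vcf"]), panel=str(paths["panel"]),
        test_regions=str(paths["test_bed"]),
        control_regions=str(paths["control_bed"]),
        out_dir=str(work / "scan"),
        populations=["pop1", "pop2"], comparisons=[("pop1", "pop2")],
    )
    result = run_scan(cfg)
    truth = {
        line.split("\t")[0]: line.split("\t")[2]
        for line in Path(paths["truth"]).read_text().splitlines()[1:]
    }
    called = {c.region_label for c in result.calls if c.verdict}
    sweep_chroms = {c for c, s in truth.items() if s == "sweep"}
    neutral_tests = [
        r.label for r in _read_bed(paths["test_bed"]) if truth.get(r.label) != "sweep"
    ]
    false_calls = sum(1 for label in neutral_tests if label in called)
    return {
        "sweep_called": sweep_chroms <= called,
        "false_call_fraction": false_calls / len(neutral_tests),
        "n_neutral_tests": len(neutral_tests),
    }


def _read_bed(path):
    from sweepscan.genomic_io import read_bed

    return read_bed(path)
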