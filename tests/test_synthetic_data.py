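import math

import numpy as np
import pytest
from scipy import stats as sps

from sweepscan import dind_test as dt
from sweepscan import fst_differentiation as fst
from sweepscan import sfs_stats as sfs
from sweepscan import synthetic_data as syn
from sweepscan.genomic_io import GenomicIOError


class TestConfig:
    def test_validation(self):
        with pytest.raises(GenomicIOError):
            syn.SimulationConfig(scenario="bogus")
        with pytest.raises(GenomicIOError):
            syn.SimulationConfig(scenario="sweep", sweep_daf=1.2)
        with pytest.raises(GenomicIOError):
            syn.SimulationConfig(scenario="sweep", compression=0.0)
        with pytest.raises(GenomicIOError):
            # fewer than 2 derived carriers
            syn.SimulationConfig(scenario="sweep", n_haplotypes=10, sweep_daf=0.05)


class TestNeutral:
    def test_determinism(self):
        cfg = syn.SimulationConfig(n_haplotypes=12, theta=4, seed=99)
        a = syn.simulate_neutral(cfg, 3)
        b = syn.simulate_neutral(cfg, 3)
        np.testing.assert_array_equal(a.data, b.data)
        assert [s.pos for s in a.sites] == [s.pos for s in b.sites]

    def test_loci_are_independent_streams(self):
        cfg = syn.SimulationConfig(n_haplotypes=12, theta=4, seed=99)
        a = syn.simulate_neutral(cfg, 0)
        b = syn.simulate_neutral(cfg, 1)
        assert a.n_sites != b.n_sites or not np.array_equal(a.data, b.data)

    def test_pairwise_diversity_expectation_n2(self):
        # E[pi] = theta; n=2 makes pi cheap and the variance explicit
        cfg = syn.SimulationConfig(n_haplotypes=2, theta=1.0, seed=5)
        pis = [sfs.theta_pi(syn.simulate_neutral(cfg, i)) for i in range(10_000)]
        assert np.mean(pis) == pytest.approx(1.0, rel=0.03)

    def test_watterson_expectation(self):
        cfg = syn.SimulationConfig(n_haplotypes=20, theta=5.0, seed=6)
        S = [syn.simulate_neutral(cfg, i).n_sites for i in range(2_000)]
        a1 = sfs.harmonic(19)
        assert np.mean(S) == pytest.approx(5.0 * a1, rel=0.02)

    def test_matrix_passes_io_invariants(self):
        cfg = syn.SimulationConfig(n_haplotypes=10, theta=8, seed=1)
        m = syn.simulate_neutral(cfg, 0)
        assert m.polarized
        counts = m.allele_counts()
        assert ((counts >= 1) & (counts <= m.n_haplotypes - 1)).all()
        pos = m.positions
        assert (np.diff(pos) > 0).all()

    def test_neutral_spectrum_one_over_i(self):
        # chi-square GOF of pooled unfolded SFS against S_i ~ 1/i
        n, theta, reps = 10, 5.0, 2_000
        cfg = syn.SimulationConfig(n_haplotypes=n, theta=theta, seed=7)
        pooled = np.zeros(n - 1)
        for i in range(reps):
            pooled += sfs.derived_count_spectrum(syn.simulate_neutral(cfg, i))
        expected = (1.0 / np.arange(1, n)) / sfs.harmonic(n - 1) * pooled.sum()
        chi2 = float(np.sum((pooled - expected) ** 2 / expected))
        p = sps.chi2.sf(chi2, df=n - 2)
        assert p > 0.01


class TestIsland:
    def _mean_fst(self, migration, reps=300, n=20, seed=13):
        cfg = syn.SimulationConfig(
            scenario="island", n_haplotypes=n, theta=5, migration=migration, seed=seed
        )
        values = []
        for i in range(reps):
            m, labels = syn.simulate_island(cfg, i)
            c1 = m.data[:n].sum(axis=0)
            c2 = m.data[n:].sum(axis=0)
            for j in range(m.n_sites):
                v = fst.wc_fst(n, c1[j] / n, n, c2[j] / n)
                if not math.isnan(v):
                    values.append(v)
        return float(np.mean(values))

    def test_panmixia_limit(self):
        assert abs(self._mean_fst(100.0, reps=200)) < 0.02

    def test_monotone_in_migration(self):
        means = [self._mean_fst(m) for m in (0.5, 2.0, 8.0)]
        assert means[0] > means[1] > means[2]

    def test_determinism(self):
        cfg = syn.SimulationConfig(scenario="island", n_haplotypes=8, theta=4,
                                   migration=1.0, seed=3)
        a, la = syn.simulate_island(cfg, 2)
        b, lb = syn.simulate_island(cfg, 2)
        np.testing.assert_array_equal(a.data, b.data)
        assert la == lb

    def test_zero_migration_rejected(self):
        cfg = syn.SimulationConfig(scenario="island", n_haplotypes=8, migration=0.0)
        with pytest.raises(GenomicIOError):
            syn.simulate_island(cfg, 0)

    def test_deme_labels(self):
        cfg = syn.SimulationConfig(scenario="island", n_haplotypes=6, theta=2,
                                   migration=1.0, seed=4)
        m, labels = syn.simulate_island(cfg, 0)
        assert labels == ["pop1"] * 6 + ["pop2"] * 6
        assert m.n_haplotypes == 12


class TestSweep:
    def test_determinism(self):
        cfg = syn.SimulationConfig(scenario="sweep", n_haplotypes=20, theta=10,
                                   compression=0.1, sweep_daf=0.8, seed=8)
        a, fa, _ = syn.simulate_sweep(cfg, 1)
        b, fb, _ = syn.simulate_sweep(cfg, 1)
        np.testing.assert_array_equal(a.data, b.data)
        assert fa == fb

    def test_focal_daf_exact(self):
        cfg = syn.SimulationConfig(scenario="sweep", n_haplotypes=20, theta=10,
                                   compression=0.05, sweep_daf=0.8, seed=9)
        m, focal, _ = syn.simulate_sweep(cfg, 0)
        assert m.derived_freqs()[focal] == pytest.approx(0.8)

    def test_c_equal_one_matches_neutral_ipid(self):
        # degenerate compression: intra-derived diversity matches a neutral
        # genealogy conditioned on the same focal DAF, within MC error
        def mean_ipid(c, seed, reps=300):
            cfg = syn.SimulationConfig(scenario="sweep", n_haplotypes=30, theta=25,
                                       compression=c, sweep_daf=0.7, seed=seed)
            vals = []
            for i in range(reps):
                m, focal, _ = syn.simulate_sweep(cfg, i)
                try:
                    _, ipid, _, _ = dt.dind_statistic(m, focal, flank=10)
                except GenomicIOError:
                    continue
                vals.append(ipid)
            return np.mean(vals), np.std(vals) / math.sqrt(len(vals))

        m1, se1 = mean_ipid(1.0, seed=20)
        m2, se2 = mean_ipid(0.999, seed=21)
        assert abs(m1 - m2) < 4 * math.hypot(se1, se2)

    def test_compression_reduces_ipid_and_raises_dind(self):
        def means(c, reps=200):
            cfg = syn.SimulationConfig(scenario="sweep", n_haplotypes=40, theta=30,
                                       compression=c, sweep_daf=0.8, seed=22)
            ipids, dinds = [], []
            for i in range(reps):
                m, focal, _ = syn.simulate_sweep(cfg, i)
                try:
                    _, ipid, dind, sentinel = dt.dind_statistic(m, focal)
                except GenomicIOError:
                    continue
                ipids.append(ipid)
                if not sentinel:
                    dinds.append(dind)
            return np.mean(ipids), np.mean(dinds)

        ipid_neutral, dind_neutral = means(1.0)
        ipid_hard, dind_hard = means(0.01)
        assert ipid_hard < ipid_neutral
        assert dind_hard > dind_neutral

    def test_two_deme_sweep_differentiates_focal(self):
        cfg = syn.SimulationConfig(scenario="sweep", n_haplotypes=20, theta=10,
                                   compression=0.05, sweep_daf=0.8,
                                   second_deme=True, migration=2.0, seed=23)
        freqs1, freqs2 = [], []
        for i in range(100):
            m, focal, labels = syn.simulate_sweep(cfg, i)
            assert labels == ["pop1"] * 20 + ["pop2"] * 20
            freqs1.append(m.data[:20, focal].mean())
            freqs2.append(m.data[20:, focal].mean())
        assert np.mean(freqs1) == pytest.approx(0.8, abs=1e-9)
        # the focal derived allele is private to deme 1 by construction
        assert np.mean(freqs2) == 0.0


class TestWriteCohort:
    def test_truth_and_aa_bookkeeping(self, tmp_path):
        cfg = syn.SimulationConfig(scenario="sweep", n_haplotypes=10, theta=6,
                                   compression=0.1, sweep_daf=0.6, seed=30)
        loci = [syn.simulate_locus(
            syn.SimulationConfig(n_haplotypes=10, theta=6, seed=30), 0),
            syn.simulate_locus(cfg, 1, role="test")]
        paths = syn.write_cohort(loci, tmp_path / "c")
        truth = (paths["truth"]).read_text().splitlines()
        assert truth[0].startswith("chrom\trole")
        assert "\ttest\tsweep\t" in truth[2]
        vcf_lines = [l for l in paths["vcf"].read_text().splitlines()
                     if not l.startswith("#")]
        for line in vcf_lines:
            fields = line.split("\t")
            assert f"AA={fields[3]}" == fields[7]  # ancestral is always REF here

    def test_bed_roles(self, tmp_path):
        loci = [syn.simulate_locus(
            syn.SimulationConfig(n_haplotypes=8, theta=4, seed=31), i,
            role="control" if i == 0 else "test") for i in range(2)]
        paths = syn.write_cohort(loci, tmp_path / "c")
        roles = [l.split("\t")[3] for l in paths["bed"].read_text().splitlines()]
        assert roles == ["control", "test"]

    def test_odd_haplotype_count_rejected(self, tmp_path):
        locus = syn.simulate_locus(
            syn.SimulationConfig(n_haplotypes=9, theta=4, seed=32), 0)
        with pytest.raises(GenomicIOError):
            syn.write_cohort([locus], tmp_path / "c")


@pytest.fixture(scope="module")
def msprime_stats():
    import msprime

    # ploidy=1 with population_size=1 gives pair-coalescence rate 1,
    # matching the package's time units (2N generations)
    n, theta, reps = 12, 6.0, 400
    S, pi = [], []
    for seed in range(1, reps + 1):
        ts = msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=1, random_seed=seed
        )
        mts = msprime.sim_mutations(
            ts, rate=theta / 2, random_seed=seed, discrete_genome=False
        )
        S.append(mts.num_sites)
        pi.append(mts.diversity(span_normalise=False))
    return {"mean_S": np.mean(S), "mean_pi": np.mean(pi)}


class TestAgainstMsprime:
    """Cross-check against an independent coalescent implementation."""

    def test_moments_agree(self, msprime_stats):
        n, theta, reps = 12, 6.0, 400
        cfg = syn.SimulationConfig(n_haplotypes=n, theta=theta, seed=40)
        S, pi = [], []
        for i in range(reps):
            m = syn.simulate_neutral(cfg, i)
            S.append(m.n_sites)
            pi.append(sfs.theta_pi(m))
        # both should match the analytic expectations within MC noise
        a1 = sfs.harmonic(n - 1)
        assert np.mean(S) == pytest.approx(theta * a1, rel=0.05)
        assert msprime_stats["mean_S"] == pytest.approx(theta * a1, rel=0.05)
        assert np.mean(S) == pytest.approx(msprime_stats["mean_S"], rel=0.07)
        assert np.mean(pi) == pytest.approx(msprime_stats["mean_pi"], rel=0.07)
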