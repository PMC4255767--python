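import math

import numpy as np
import pytest

from sweepscan import sfs_stats as sfs
from sweepscan.genomic_io import GenomicIOError, Region

from .conftest import make_matrix, random_matrix


# ---- independent oracles (kept deliberately naive) --------------------


def pairwise_pi_oracle(data: np.ndarray) -> float:
    """O(n^2 S) direct pairwise-difference count."""
    n = data.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(data[i] != data[j]))
            pairs += 1
    return total / pairs


def tajimas_d_oracle(data: np.ndarray) -> float:
    """Brute-force re-derivation of the 1989 statistic, written separately."""
    n = data.shape[0]
    counts = data.sum(axis=0)
    S = int(np.sum((counts > 0) & (counts < n)))
    if S == 0:
        return math.nan
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pairwise_pi_oracle(data) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestSpectrum:
    def test_three_singletons(self, three_singletons):
        np.testing.assert_array_equal(
            sfs.derived_count_spectrum(three_singletons), [3, 0, 0]
        )

    def test_monomorphic_only(self):
        m = make_matrix([[0, 1], [0, 1], [0, 1], [0, 1]])
        np.testing.assert_array_equal(sfs.derived_count_spectrum(m), [0, 0, 0])

    def test_sums_to_polymorphic_columns(self, rng):
        m = random_matrix(rng, n_hap=20, n_site=50)
        counts = m.data.sum(axis=0)
        expected = int(np.sum((counts > 0) & (counts < 20)))
        assert sfs.derived_count_spectrum(m).sum() == expected

    def test_unpolarized_rejected(self, rng):
        m = random_matrix(rng, polarized=False)
        with pytest.raises(GenomicIOError):
            sfs.derived_count_spectrum(m)


class TestThetaPi:
    def test_identical_haplotypes(self):
        m = make_matrix([[1, 0, 1]] * 4)
        assert sfs.theta_pi(m) == 0.0

    def test_single_pair(self):
        m = make_matrix([[1, 1, 1, 1, 1], [0, 0, 0, 0, 0]])
        assert sfs.theta_pi(m) == 5.0

    def test_three_singletons(self, three_singletons):
        assert sfs.theta_pi(three_singletons) == pytest.approx(1.5)

    def test_matches_pairwise_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 15))
            s = int(rng.integers(1, 30))
            m = random_matrix(rng, n_hap=n, n_site=s)
            assert sfs.theta_pi(m) == pytest.approx(
                pairwise_pi_oracle(m.data), abs=1e-9
            )

    def test_row_permutation_invariance(self, rng):
        m = random_matrix(rng, n_hap=10, n_site=20)
        perm = m.take_haplotypes(rng.permutation(10))
        assert sfs.theta_pi(perm) == pytest.approx(sfs.theta_pi(m), abs=1e-12)
        assert sfs.tajimas_d(perm) == pytest.approx(sfs.tajimas_d(m), abs=1e-12)
        assert sfs.normalized_dh(perm) == pytest.approx(sfs.normalized_dh(m), abs=1e-12)


class TestThetaW:
    def test_zero_sites(self):
        assert sfs.theta_w(0, 10) == 0.0

    def test_n2_identity(self):
        assert sfs.theta_w(5, 2) == pytest.approx(5.0)

    def test_n4(self):
        assert sfs.theta_w(3, 4) == pytest.approx(3 / (1 + 0.5 + 1 / 3), abs=1e-9)
        assert sfs.theta_w(3, 4) == pytest.approx(1.636364, abs=1e-6)

    def test_too_few_haplotypes(self):
        with pytest.raises(GenomicIOError):
            sfs.theta_w(3, 1)


class TestTajimasD:
    def test_zero_when_pi_equals_theta_w(self):
        # n=4 with 8 singletons and 3 doubletons: pi = theta_W = 6 exactly
        cols = []
        for i in range(8):
            col = [0, 0, 0, 0]
            col[i % 4] = 1
            cols.append(col)
        for i in range(3):
            col = [0, 0, 0, 0]
            col[i % 4] = 1
            col[(i + 1) % 4] = 1
            cols.append(col)
        m = make_matrix(np.array(cols, dtype=np.uint8).T.tolist())
        assert sfs.theta_pi(m) == pytest.approx(sfs.theta_w(11, 4), abs=1e-12)
        assert sfs.tajimas_d(m) == pytest.approx(0.0, abs=1e-12)

    def test_no_segregating_sites(self):
        m = make_matrix([[0, 0], [0, 0], [0, 0], [0, 0]])
        assert math.isnan(sfs.tajimas_d(m))

    def test_three_singletons_frozen_value(self, three_singletons):
        # frozen from tajimas_d_oracle on this configuration
        assert sfs.tajimas_d(three_singletons) == pytest.approx(-0.7544511, abs=1e-6)
        assert sfs.tajimas_d(three_singletons) == pytest.approx(
            tajimas_d_oracle(three_singletons.data), abs=1e-12
        )

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            m = random_matrix(rng, n_hap=int(rng.integers(4, 12)), n_site=20)
            got = sfs.tajimas_d(m)
            want = tajimas_d_oracle(m.data)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)


class TestFayWuH:
    def test_three_singletons(self, three_singletons):
        theta_l, H = sfs.fay_wu_h(three_singletons)
        assert theta_l == pytest.approx(1.0)
        assert H == pytest.approx(1.0)

    def test_high_frequency_site(self, one_high_freq_site):
        theta_l, H = sfs.fay_wu_h(one_high_freq_site)
        assert theta_l == pytest.approx(1.0)
        assert sfs.theta_pi(one_high_freq_site) == pytest.approx(0.5)
        assert H == pytest.approx(-1.0)

    def test_empty(self):
        m = make_matrix([[0], [0], [0], [0]])
        _, H = sfs.fay_wu_h(m)
        assert H == 0.0

    def test_two_definitions_agree(self, rng):
        for _ in range(100):
            m = random_matrix(rng, n_hap=int(rng.integers(3, 15)), n_site=25)
            _, H = sfs.fay_wu_h(m)
            assert H == pytest.approx(
                sfs.theta_pi(m) - sfs.theta_h(m), abs=1e-9
            )


class TestNormalizedDH:
    def test_nan_when_no_segregation(self):
        m = make_matrix([[0], [0], [0], [0]])
        assert math.isnan(sfs.normalized_dh(m))

    def test_sign_forced_by_high_frequency_derived(self, one_high_freq_site):
        assert sfs.normalized_dh(one_high_freq_site) < 0

    def test_magnitude_against_independent_variance(self, one_high_freq_site):
        # independent transcription of the Zeng et al. (2006) variance
        n, S = 4, 1
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        bn1 = sum(1 / i**2 for i in range(1, n + 1))
        theta = S / a1
        theta2 = S * (S - 1) / (a1**2 + a2)
        var = (n - 2) / (6 * (n - 1)) * theta + (
            18 * n**2 * (3 * n + 2) * bn1 - (88 * n**3 + 9 * n**2 - 13 * n + 6)
        ) / (9 * n * (n - 1) ** 2) * theta2
        pi = sfs.theta_pi(one_high_freq_site)
        theta_l = 1.0
        assert sfs.normalized_dh(one_high_freq_site) == pytest.approx(
            (pi - theta_l) / math.sqrt(var), abs=1e-12
        )


class TestSlidingWindows:
    def test_window_count(self, rng):
        region = Region("chr1", 0, 10_000)
        m = random_matrix(rng, n_hap=6, n_site=30)
        records = sfs.sliding_windows(region, m, window=5_000, step=500)
        assert len(records) == 11  # floor((10000-5000)/500)+1

    def test_empty_window_is_na(self):
        region = Region("chr1", 0, 5_000)
        m = make_matrix([[1], [0]], start_pos=999_999)
        (rec,) = sfs.sliding_windows(region, m, window=5_000, step=500)
        assert rec.n_snps == 0 and rec.S == 0
        assert math.isnan(rec.tajimas_d) and math.isnan(rec.DH)

    def test_single_window_equals_region_stats(self, rng):
        m = random_matrix(rng, n_hap=8, n_site=40, polarized=True)
        region = Region("chr1", 0, 1_000)
        (win,) = sfs.sliding_windows(region, m, window=1_000, step=1_000, min_snps=1)
        whole = sfs.region_stats(region, m)
        assert win.S == whole.S
        assert win.pi == pytest.approx(whole.pi)
        assert win.tajimas_d == pytest.approx(whole.tajimas_d)
        assert win.DH == pytest.approx(whole.DH)

    def test_short_region_single_truncated_window(self, rng):
        m = random_matrix(rng, n_hap=6, n_site=10)
        records = sfs.sliding_windows(Region("chr1", 0, 3_000), m, window=5_000, step=500)
        assert len(records) == 1
        assert records[0].truncated

    def test_min_snps_gate(self, rng):
        region = Region("chr1", 0, 1_000)
        m = random_matrix(rng, n_hap=6, n_site=5)
        (rec,) = sfs.sliding_windows(region, m, window=1_000, step=1_000, min_snps=10)
        assert math.isnan(rec.tajimas_d)

    def test_bad_window_step(self, rng):
        m = random_matrix(rng)
        with pytest.raises(GenomicIOError):
            sfs.sliding_windows(Region("chr1", 0, 10_000), m, window=100, step=500)

    def test_tsv_output(self, tmp_path, rng):
        m = random_matrix(rng, n_hap=6, n_site=30)
        records = sfs.sliding_windows(Region("chr1", 0, 10_000), m, population="P")
        out = tmp_path / "win.tsv"
        sfs.window_records_to_tsv(records, out, "# test")
        lines = out.read_text().splitlines()
        assert lines[0] == "# test"
        assert len(lines) == len(records) + 2
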