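"""Distance-dependent correlations, spectra and recurrence plots."""

import numpy as np
import pandas as pd
import pytest

from methylhet import distcorr
from methylhet.readstats import ReadMethVector
from conftest import random_read_vector


def _brute_force_rho_d(vec, d_min, d_max):
    """O(N^2) oracle: enumerate all pairs, Pearson per exact distance."""
    out = np.full(d_max - d_min + 1, np.nan)
    pos, v = vec.positions, vec.states.astype(float)
    n = len(pos)
    for d in range(d_min, d_max + 1):
        xs, ys = [], []
        for i in range(n - 1):
            for j in range(i + 1, n):
                if pos[j] - pos[i] == d:
                    xs.append(v[i])
                    ys.append(v[j])
        if len(xs) >= 2:
            x, y = np.array(xs), np.array(ys)
            denom = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            if denom > 0:
                out[d - d_min] = ((x - x.mean()) * (y - y.mean())).sum() / denom
    return out


class TestReadDistanceCorrelation:
    def test_matches_brute_force_oracle_on_random_reads(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            vec = random_read_vector(rng, n_sites=int(rng.integers(20, 80)), spacing=8)
            got = distcorr.read_distance_correlation(vec, 2, 60)
            want = _brute_force_rho_d(vec, 2, 60)
            assert np.allclose(got, want, atol=1e-12, equal_nan=True)

    def test_periodic_read_has_signed_peaks(self):
        # alternating 95 bp half-period blocks: anti-correlated at 95 bp,
        # correlated at the 190 bp full period
        positions = np.arange(0, 4000, 5).astype(np.int64)
        states = ((positions // 95) % 2).astype(np.uint8)
        vec = ReadMethVector("r", "c", 0, 4000, positions, states)
        rho = distcorr.read_distance_correlation(vec, 2, 250)
        d = np.arange(2, 251)
        assert rho[d == 190][0] > 0.8
        assert rho[d == 95][0] < -0.8

    def test_constant_read_undefined_everywhere(self):
        positions = np.arange(0, 500, 5).astype(np.int64)
        vec = ReadMethVector("r", "c", 0, 500, positions, np.ones(100, dtype=np.uint8))
        rho = distcorr.read_distance_correlation(vec, 2, 50)
        assert np.isnan(rho).all()

    def test_mean_over_single_read_equals_read_profile(self):
        rng = np.random.default_rng(3)
        vec = random_read_vector(rng, n_sites=60, spacing=10)
        prof = distcorr.mean_distance_correlation([vec], 2, 80)
        rho = distcorr.read_distance_correlation(vec, 2, 80)
        assert np.allclose(prof["mean_rho"].to_numpy(), rho, equal_nan=True)

    def test_iid_reads_give_flat_profile(self):
        rng = np.random.default_rng(4)
        reads = [random_read_vector(rng, n_sites=400, spacing=10) for _ in range(200)]
        prof = distcorr.mean_distance_correlation(reads, 2, 100)
        vals = prof["mean_rho"].dropna()
        assert abs(vals.mean()) < 0.02


class TestCrossDistanceCorrelation:
    def test_perfectly_coupled_tracks_positive_at_small_distance(self):
        # both motifs driven by the same 190 bp square wave
        rng = np.random.default_rng(5)
        pos_a = np.sort(rng.choice(np.arange(0, 6000, 3), 500, replace=False)).astype(np.int64)
        pos_b = pos_a + 1  # interleaved second motif
        wave = lambda p: ((p // 95) % 2).astype(np.uint8)
        rho = distcorr.cross_distance_correlation(pos_a, wave(pos_a), pos_b, wave(pos_b), 1, 250)
        d = np.arange(1, 251)
        assert rho[d == 1][0] > 0.8
        assert rho[d == 190][0] > 0.5
        assert rho[d == 95][0] < -0.5


class TestWavelength:
    @pytest.mark.parametrize(
        "omega,expected", [(0.0335, 187.6), (0.0357, 176.0), (0.0313, 200.7)]
    )
    def test_printed_conversions(self, omega, expected):
        assert distcorr.wavelength_from_frequency(omega) == expected

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            distcorr.wavelength_from_frequency(0.0)


class TestPowerSpectrum:
    def _profile(self, values, d0=2):
        d = np.arange(d0, d0 + len(values))
        return pd.DataFrame({"d": d, "mean_rho": values})

    def test_pure_cosine_peak_location(self):
        d = np.arange(2, 2001)
        prof = self._profile(np.cos(2 * np.pi * d / 187.6))
        res = distcorr.power_spectrum(prof)
        assert res.significant
        assert res.omega_peak == pytest.approx(2 * np.pi / 187.6, abs=2 * 2 * np.pi / len(d))
        lo, hi = res.lambda_range
        assert lo < 187.6 < hi

    def test_white_noise_not_significant(self):
        rng = np.random.default_rng(0)
        prof = self._profile(rng.normal(0, 0.01, 1999))
        res = distcorr.power_spectrum(prof)
        assert not res.significant

    def test_constant_profile_empty_result(self):
        prof = self._profile(np.full(500, 0.25))
        res = distcorr.power_spectrum(prof)
        assert not res.significant and np.isnan(res.omega_peak)

    def test_near_zero_frequency_peak_discarded_as_nonphysical(self):
        # a strong slow trend (apparent wavelength far beyond the profile)
        # produces a dominant near-zero-frequency peak; it must be discarded
        # and the genuine ~190 bp oscillation reported instead
        d = np.arange(2, 2001)
        prof = self._profile(np.cos(2 * np.pi * d / 8000) + 0.3 * np.cos(2 * np.pi * d / 190))
        res = distcorr.power_spectrum(prof)
        assert res.significant
        assert 150 < res.lambda_peak < 250

    def test_missing_values_interpolated(self):
        d = np.arange(2, 1001)
        vals = np.cos(2 * np.pi * d / 190.0)
        vals[::37] = np.nan
        res = distcorr.power_spectrum(self._profile(vals))
        assert res.n_interpolated > 0
        assert res.significant
        assert res.lambda_peak == pytest.approx(190, rel=0.03)

    def test_half_maximum_band_brackets_peak(self):
        d = np.arange(2, 2001)
        rng = np.random.default_rng(1)
        prof = self._profile(np.cos(2 * np.pi * d / 190) + rng.normal(0, 0.05, len(d)))
        res = distcorr.power_spectrum(prof)
        assert res.omega_min <= res.omega_peak <= res.omega_max


class TestBulkSynthetic:
    def _sites(self, states_by_site):
        rows = []
        for pos, states in states_by_site.items():
            for k, s in enumerate(states):
                rows.append(("chr1", pos, f"r{k}", "CpG", s))
        return pd.DataFrame(rows, columns=["chrom", "pos", "read_id", "motif", "state"]).astype(
            {"state": np.int8}
        )

    def test_trinomial_proportions(self):
        sites = self._sites({10: [1, 1, 1, 0, -1]})
        probs = distcorr.bulk_site_probabilities(sites)
        row = probs.loc[("chr1", 10)]
        assert row["mu_u"] == pytest.approx(0.2)
        assert row["mu_m"] == pytest.approx(0.6)
        assert row["mu_na"] == pytest.approx(0.2)

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(2)
        sites = self._sites({p: rng.choice([-1, 0, 1], 20) for p in range(0, 100, 10)})
        probs = distcorr.bulk_site_probabilities(sites)
        assert np.allclose(probs[["mu_u", "mu_m", "mu_na"]].sum(axis=1), 1.0)

    def test_assigned_fraction_matches_site_bulk_m(self):
        from methylhet import windows

        sites = self._sites({10: [1] * 6 + [0] * 4 + [-1] * 5})
        probs = distcorr.bulk_site_probabilities(sites)
        row = probs.loc[("chr1", 10)]
        m_from_probs = row["mu_m"] / (row["mu_m"] + row["mu_u"])
        win = windows.make_windows({"chr1": 1000}, 1000)
        sb = windows.site_bulk_levels(sites, win, min_coverage=1)
        assert m_from_probs == pytest.approx(sb.iloc[0]["m"])

    def test_deterministic_site_always_methylated(self):
        sites = self._sites({10: [1, 1, 1]})
        probs = distcorr.bulk_site_probabilities(sites)
        synth = distcorr.synthesize_reads_from_bulk(sites, probs, np.random.default_rng(0))
        assert (synth["state"] == 1).all()

    def test_synthetic_fraction_within_binomial_ci(self):
        sites = self._sites({10: [1] * 6 + [0] * 4})
        probs = distcorr.bulk_site_probabilities(sites)
        big = pd.concat([sites] * 1000, ignore_index=True)
        synth = distcorr.synthesize_reads_from_bulk(big, probs, np.random.default_rng(1))
        assert (synth["state"] == 1).mean() == pytest.approx(0.6, abs=0.02)


class TestRecurrence:
    def test_symmetric_with_similar_diagonal(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.1, 50)
        m = distcorr.recurrence_matrix(vals, 0.06)
        assert np.array_equal(m, m.T)
        assert m.diagonal().all()

    def test_constant_profile_all_similar(self):
        m = distcorr.recurrence_matrix(np.full(20, 0.5), 0.06)
        assert m.all()

    def test_epsilon_above_range_all_similar(self):
        vals = np.linspace(0, 0.1, 30)
        assert distcorr.recurrence_matrix(vals, 0.2).all()

    def test_difference_distance_is_hamming_root(self):
        rng = np.random.default_rng(4)
        a = rng.random((30, 30)) > 0.5
        b = rng.random((30, 30)) > 0.5
        diff, dist = distcorr.recurrence_difference(a, b)
        assert dist == pytest.approx(np.sqrt((a != b).sum()))
        assert diff.sum() == (a != b).sum()

    def test_identical_matrices_zero_distance(self):
        a = np.ones((10, 10), dtype=bool)
        _, dist = distcorr.recurrence_difference(a, a.copy())
        assert dist == 0.0

    def test_complementary_matrices_full_distance(self):
        a = np.zeros((10, 10), dtype=bool)
        _, dist = distcorr.recurrence_difference(a, ~a)
        assert dist == pytest.approx(np.sqrt(100))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distcorr.recurrence_difference(np.ones((3, 3), bool), np.ones((4, 4), bool))


class TestSelectEpsilon:
    def test_identical_profiles_return_smallest_grid_value(self):
        vals = np.linspace(0, 1, 40)
        eps, dist = distcorr.select_epsilon(vals, vals.copy(), np.array([0.01, 0.05, 0.1]))
        assert eps == 0.01 and dist == 0.0

    def test_single_grid_value(self):
        rng = np.random.default_rng(5)
        eps, _ = distcorr.select_epsilon(rng.random(20), rng.random(20), np.array([0.06]))
        assert eps == 0.06

    def test_returned_epsilon_attains_grid_maximum(self):
        rng = np.random.default_rng(6)
        real = np.cos(np.linspace(0, 12, 80)) * 0.2
        synth = rng.normal(0, 0.05, 80)
        grid = np.arange(0.01, 0.21, 0.01)
        eps, dist = distcorr.select_epsilon(real, synth, grid)
        for e in grid:
            _, d = distcorr.recurrence_difference(
                distcorr.recurrence_matrix(real, e), distcorr.recurrence_matrix(synth, e)
            )
            assert d <= dist


class TestOscillationMagnitude:
    def _profiles(self, scale=1.0, n=1800, period=190):
        d = np.arange(2, 2 + n)
        real = 0.3 * np.cos(2 * np.pi * d / period) * np.exp(-d / 2000)
        synth = scale * real
        return (
            pd.DataFrame({"d": d, "mean_rho": real}),
            pd.DataFrame({"d": d, "mean_rho": synth}),
        )

    def test_equal_profiles_p_one(self):
        real, synth = self._profiles(scale=1.0)
        rep = distcorr.compare_oscillation_magnitude(real, synth)
        assert rep["p_value"] == 1.0

    def test_halved_amplitude_detected(self):
        real, synth = self._profiles(scale=0.5)
        rep = distcorr.compare_oscillation_magnitude(real, synth)
        assert not rep["underpowered"]
        assert (rep["amplitudes_synth"] < rep["amplitudes_real"]).all()
        assert rep["p_value"] < 0.05

    def test_amplitudes_non_negative(self):
        real, synth = self._profiles(scale=0.7)
        rep = distcorr.compare_oscillation_magnitude(real, synth)
        assert (rep["amplitudes_real"] >= 0).all()
        assert (rep["amplitudes_synth"] >= 0).all()

    def test_too_few_cycles_flagged(self):
        real, synth = self._profiles(n=250)
        rep = distcorr.compare_oscillation_magnitude(real, synth)
        assert rep["underpowered"] or rep["n_cycles"] >= 3
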