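import numpy as np
import pandas as pd
import pytest

from simrecall._grid import BIN_CENTERS, N_BINS, nearest_bin
from simrecall.neural_resource import PopulationParams
from simrecall.scaling import build_similarity_function
from simrecall.tcc import (D_PRIME_GRID, EXPONENT_GRID, VM_SD_GRID, TCCParams,
                           fit_empirical_tcc, fit_synthetic_tcc,
                           fit_vonmises_tcc, kappa_from_circular_sd,
                           mean_signal, nr_to_tcc_equivalent, report_pmf,
                           sample_reports, vonmises_responsiveness)

from conftest import simulate_tcc_trials


def test_printed_grids():
    assert D_PRIME_GRID[0] == 0.0 and D_PRIME_GRID[-1] == 5.5
    assert np.allclose(np.diff(D_PRIME_GRID), 0.02)
    assert EXPONENT_GRID[0] == 0.001 and np.allclose(np.diff(EXPONENT_GRID), 0.0313)
    assert EXPONENT_GRID[-1] <= 10.0 < EXPONENT_GRID[-1] + 0.0313
    assert VM_SD_GRID[0] == 0.03 and np.allclose(np.diff(VM_SD_GRID), 0.0062)
    assert VM_SD_GRID[-1] <= 2.0 < VM_SD_GRID[-1] + 0.0062


class TestMeanSignal:
    def test_zero_dprime_is_zero_vector(self, color_omega):
        assert np.all(mean_signal(color_omega.values, 0.0) == 0.0)

    def test_peak_equals_dprime(self, color_omega):
        sig = mean_signal(color_omega.values, 2.3)
        assert sig.max() == pytest.approx(2.3)
        assert sig[180] == pytest.approx(2.3)  # offset 0

    def test_elementwise_product(self):
        resp = 1.0 - np.abs(BIN_CENTERS) / np.pi  # linear-in-distance curve
        sig = mean_signal(resp, 2.0)
        for idx in (0, 90, 180, 270):
            assert sig[idx] == pytest.approx(2.0 * resp[idx])

    def test_negative_dprime_rejected(self):
        with pytest.raises(ValueError):
            mean_signal(np.ones(N_BINS), -0.1)


class TestReportPmf:
    def test_zero_signal_uniform(self, color_omega):
        pmf = report_pmf(mean_signal(color_omega.values, 0.0)).pmf
        np.testing.assert_allclose(pmf, 1 / N_BINS, atol=1e-12)

    def test_normalized_and_symmetric(self, color_omega):
        dist = report_pmf(mean_signal(color_omega.values, 2.0))
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(dist.pmf[1:], dist.pmf[1:][::-1], atol=1e-12)
        assert np.argmax(dist.pmf) == 180  # mode at zero error

    def test_matches_monte_carlo_max_rule(self, color_omega):
        sig = mean_signal(color_omega.values, 2.0)
        dist = report_pmf(sig, 2.0)
        rng = np.random.default_rng(0)
        errs = sample_reports(sig, 2.0, 200_000, rng)
        hist = np.bincount(nearest_bin(errs), minlength=N_BINS) / 200_000
        assert 0.5 * np.abs(dist.pmf - hist).sum() < 0.012

    def test_quadrature_node_invariance(self, color_omega):
        sig = mean_signal(color_omega.values, 2.0)
        a = report_pmf(sig, quad_nodes=220).pmf
        b = report_pmf(sig, quad_nodes=2000).pmf
        assert 0.5 * np.abs(a - b).sum() < 1e-10


class TestVonMisesResponsiveness:
    def test_unit_peak(self):
        resp = vonmises_responsiveness(0.5)
        assert resp[180] == pytest.approx(1.0) and resp.max() == 1.0

    def test_circular_sd_round_trip(self):
        from scipy.special import ive
        for sd in (0.1, 0.5, 1.5):
            k = kappa_from_circular_sd(sd)
            r = ive(1, k) / ive(0, k)
            assert np.sqrt(-2 * np.log(r)) == pytest.approx(sd, rel=1e-8)


class TestFitEmpiricalTCC:
    def test_recovery_within_two_grid_steps(self, color_omega):
        rng = np.random.default_rng(3)
        wm = simulate_tcc_trials(color_omega.values, {3: 2.0}, 5000, rng)
        fit = fit_empirical_tcc(wm, color_omega)
        assert abs(fit.params.d_prime_by_setsize[3] - 2.0) <= 0.04 + 1e-9

    def test_windowed_search_equals_exhaustive(self, color_omega):
        rng = np.random.default_rng(5)
        wm = simulate_tcc_trials(color_omega.values, {3: 1.4, 6: 0.8}, 400, rng)
        fast = fit_empirical_tcc(wm, color_omega)
        full = fit_empirical_tcc(wm, color_omega, exhaustive=True)
        assert fast.params.d_prime_by_setsize == full.params.d_prime_by_setsize

    def test_uniform_responses_give_zero_dprime(self, color_omega):
        rng = np.random.default_rng(6)
        wm = pd.DataFrame({"set_size": 3,
                           "error": rng.uniform(-np.pi, np.pi, 600)})
        fit = fit_empirical_tcc(wm, color_omega)
        assert fit.params.d_prime_by_setsize[3] == 0.0

    def test_per_setsize_independence(self, color_omega):
        rng = np.random.default_rng(7)
        wm = simulate_tcc_trials(color_omega.values, {3: 3.0, 6: 1.5}, 5000, rng)
        d = fit_empirical_tcc(wm, color_omega).params.d_prime_by_setsize
        assert abs(d[3] - 3.0) <= 0.04 + 1e-9
        assert abs(d[6] - 1.5) <= 0.04 + 1e-9
        assert d[3] > d[6]

    def test_aic_counts_two_parameters(self, color_omega):
        rng = np.random.default_rng(8)
        wm = simulate_tcc_trials(color_omega.values, {3: 2.0, 6: 1.0}, 100, rng)
        fit = fit_empirical_tcc(wm, color_omega)
        assert fit.aic == pytest.approx(4 - 2 * fit.log_likelihood)

    def test_fitted_dprime_monotone_in_data_concentration(self, color_omega):
        rng = np.random.default_rng(9)
        fitted = []
        for d_true in (0.5, 1.25, 2.0, 2.75, 3.5):
            wm = simulate_tcc_trials(color_omega.values, {3: d_true}, 800, rng)
            fitted.append(fit_empirical_tcc(wm, color_omega)
                          .params.d_prime_by_setsize[3])
        assert np.all(np.diff(fitted) > 0)


class TestFitSyntheticTCC:
    def test_recovery(self):
        om = build_similarity_function(1.5, 0.103)
        rng = np.random.default_rng(12)
        wm = simulate_tcc_trials(om.values, {3: 2.5, 6: 1.8}, 1000, rng)
        fit = fit_synthetic_tcc(wm, 0.103)
        assert abs(fit.params.shape_param - 1.5) <= 0.5
        assert abs(fit.params.d_prime_by_setsize[3] - 2.5) <= 0.1
        assert abs(fit.params.d_prime_by_setsize[6] - 1.8) <= 0.1
        assert fit.aic == pytest.approx(6 - 2 * fit.log_likelihood)

    def test_returned_exponent_beats_grid_neighbors(self, color_omega):
        rng = np.random.default_rng(13)
        wm = simulate_tcc_trials(color_omega.values, {3: 2.0, 6: 1.2}, 300, rng)
        fit = fit_synthetic_tcc(wm, 0.103)
        i = int(np.argmin(np.abs(EXPONENT_GRID - fit.params.shape_param)))

        def joint_ll(exponent):
            resp = build_similarity_function(exponent, 0.103).values
            f = fit_empirical_tcc(wm, resp)
            return f.log_likelihood

        best = joint_ll(EXPONENT_GRID[i])
        for j in (i - 1, i + 1):
            assert best >= joint_ll(EXPONENT_GRID[j]) - 1e-9

    def test_fixed_exponent_reduces_to_empirical_fit(self, color_omega):
        """With the exponent grid pinned to the observer's measured tau,
        the synthetic fit reproduces the empirical fit exactly."""
        rng = np.random.default_rng(14)
        wm = simulate_tcc_trials(color_omega.values, {3: 2.0, 6: 1.2}, 300, rng)
        emp = fit_empirical_tcc(wm, color_omega)
        syn = fit_synthetic_tcc(wm, 0.103,
                                exponent_grid=np.array([color_omega.tau]))
        assert syn.params.d_prime_by_setsize == emp.params.d_prime_by_setsize
        assert syn.log_likelihood == pytest.approx(emp.log_likelihood)
        assert syn.aic == pytest.approx(emp.aic + 2)  # one extra parameter


class TestFitVonMisesTCC:
    def test_recovery(self):
        rng = np.random.default_rng(15)
        resp = vonmises_responsiveness(0.5)
        wm = simulate_tcc_trials(resp, {3: 2.5, 6: 1.8}, 1000, rng)
        fit = fit_vonmises_tcc(wm)
        assert abs(fit.params.shape_param - 0.5) <= 0.05
        assert abs(fit.params.d_prime_by_setsize[3] - 2.5) <= 0.1
        assert abs(fit.params.d_prime_by_setsize[6] - 1.8) <= 0.1

    def test_broad_curve_high_dprime_near_normal(self):
        """A broad responsiveness curve with strong signal predicts an
        error distribution with little excess kurtosis (limit behavior,
        evaluated beyond the fitting grid's amplitude cap)."""
        resp = vonmises_responsiveness(1.9)
        dist = report_pmf(mean_signal(resp, 8.0))
        m2 = np.sum(dist.pmf * dist.bin_centers**2)
        m4 = np.sum(dist.pmf * dist.bin_centers**4)
        assert m4 / m2**2 - 3.0 < 0.2


class TestNRToTCCMapping:
    def test_zero_activity_maps_to_zero_signal(self):
        mapped = nr_to_tcc_equivalent(PopulationParams(0.0, 4.0, 1))
        assert mapped.d_prime_by_setsize == {3: 0.0, 6: 0.0}

    def test_set_size_scaling_is_sqrt2(self):
        mapped = nr_to_tcc_equivalent(PopulationParams(60.0, 4.0, 3))
        d = mapped.d_prime_by_setsize
        assert d[3] / d[6] == pytest.approx(np.sqrt(2))

    def test_mapped_pmf_matches_gaussian_population_simulation(self):
        """The quadrature pmf of the mapped signal-detection model agrees
        with direct simulation of the unit-variance Gaussian population
        under the max rule."""
        mapped = nr_to_tcc_equivalent(PopulationParams(60.0, 4.0, 3))
        sig = mean_signal(mapped.responsiveness, mapped.d_prime_by_setsize[3])
        dist = report_pmf(sig, motor_sd_deg=0.0)
        rng = np.random.default_rng(1)
        errs = sample_reports(sig, 0.0, 300_000, rng)
        hist = np.bincount(nearest_bin(errs), minlength=N_BINS) / 300_000
        assert 0.5 * np.abs(dist.pmf - hist).sum() < 0.012

    def test_fitted_ratio_tracks_sample_size_prediction(self):
        """Fitting per-set-size amplitudes to data generated from the
        Gaussian-noise population variant recovers d'3/d'6 = sqrt(2)."""
        mapped = nr_to_tcc_equivalent(PopulationParams(60.0, 4.0, 3))
        ratios = []
        for s in range(6):
            rng = np.random.default_rng(40 + s)
            wm = simulate_tcc_trials(mapped.responsiveness,
                                     mapped.d_prime_by_setsize, 200, rng,
                                     motor_sd_deg=0.0)
            f = fit_empirical_tcc(wm, mapped.responsiveness, motor_sd_deg=0.0)
            d = f.params.d_prime_by_setsize
            ratios.append(d[3] / d[6])
        assert np.mean(ratios) == pytest.approx(np.sqrt(2), rel=0.15)


def test_tcc_params_validation(color_omega):
    with pytest.raises(ValueError):
        TCCParams("bogus", {3: 1.0}, color_omega.values)
    with pytest.raises(ValueError):
        TCCParams("empirical", {3: -1.0}, color_omega.values)
    with pytest.raises(ValueError):
        TCCParams("empirical", {3: 1.0}, 0.5 * color_omega.values)
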