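import numpy as np
import pandas as pd
import pytest
from scipy.special import ive

from simrecall._grid import N_BINS, nearest_bin
from simrecall.neural_resource import (PopulationParams, fit_neural_resource,
                                       kappa_to_width, ml_decode, mean_rates,
                                       nr_error_distribution, rmax_from,
                                       sample_spikes, width_to_kappa)

from conftest import simulate_nr_trials


class TestMeanRates:
    def test_peak_at_preferred_value(self):
        p = PopulationParams(50.0, 4.0, 1, m_neurons=100)
        phi = p.preferred_values
        rates = mean_rates(phi[37], p)
        assert np.argmax(rates) == 37
        expected_peak = 50.0 / 100 * np.exp(4.0) / (ive(0, 4.0) * np.exp(4.0))
        assert rates[37] == pytest.approx(expected_peak)

    def test_flat_tuning_at_zero_kappa(self):
        p = PopulationParams(50.0, 0.0, 2, m_neurons=64)
        rates = mean_rates(0.3, p)
        np.testing.assert_allclose(rates, 50.0 / (64 * 2))

    def test_population_rate_sums_to_gamma(self):
        # Riemann sum of the von Mises density over the uniform tiling
        p = PopulationParams(50.0, 4.0, 1, m_neurons=100)
        assert mean_rates(1.234, p).sum() == pytest.approx(50.0, rel=0.01)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            PopulationParams(50.0, -1.0, 1)


class TestSampleSpikes:
    def test_zero_rate_never_spikes(self):
        rng = np.random.default_rng(0)
        assert np.all(sample_spikes(np.zeros(10), 1.0, rng) == 0)

    def test_poisson_moments(self):
        rng = np.random.default_rng(1)
        counts = sample_spikes(np.full(100_000, 3.0), 1.0, rng)
        se = np.sqrt(3.0 / 100_000)
        assert abs(counts.mean() - 3.0) < 3 * se
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)


class TestMLDecode:
    def test_single_active_neuron(self):
        phi = np.array([-1.0, 0.5, 2.0])
        est, guessed = ml_decode(np.array([0, 7, 0]), phi, 4.0)
        assert est == pytest.approx(0.5) and not guessed

    def test_symmetric_counts_decode_to_zero(self):
        phi = np.array([-0.8, 0.8])
        est, _ = ml_decode(np.array([3, 3]), phi, 4.0)
        assert est == pytest.approx(0.0)

    def test_zero_spikes_flagged_uniform(self):
        rng = np.random.default_rng(2)
        est, guessed = ml_decode(np.zeros(5), np.linspace(-3, 3, 5), 4.0,
                                 rng=rng)
        assert guessed and -np.pi <= est < np.pi

    def test_matches_poisson_likelihood_grid_argmax(self):
        """Resultant direction equals brute-force argmax of the exact
        Poisson log likelihood on a dense stimulus grid (100 cases)."""
        rng = np.random.default_rng(3)
        m = 12
        phi = -np.pi + np.arange(m) * 2 * np.pi / m
        grid = np.linspace(-np.pi, np.pi, 10_000, endpoint=False)
        for _ in range(100):
            counts = rng.poisson(1.5, m)
            if counts.sum() == 0:
                continue
            kappa = rng.uniform(0.5, 8.0)
            # exact log likelihood: sum_i n_i * kappa * cos(theta - phi_i) + const
            ll = (counts * np.cos(grid[:, None] - phi[None, :]) * kappa).sum(axis=1)
            brute = grid[np.argmax(ll)]
            est, _ = ml_decode(counts, phi, kappa)
            assert abs(np.angle(np.exp(1j * (est - brute)))) < 2 * np.pi / 10_000 + 1e-9

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            ml_decode(np.ones(3), np.ones(4), 1.0)


class TestWidthReparameterization:
    def test_half_log2_gives_pi(self):
        assert kappa_to_width(np.log(2)) == pytest.approx(np.pi)

    def test_round_trip(self):
        for kappa in np.geomspace(0.7, 50, 20):
            assert width_to_kappa(kappa_to_width(kappa)) == pytest.approx(
                kappa, abs=1e-10, rel=1e-10)

    def test_width_decreasing_in_kappa(self):
        ks = np.linspace(0.5, 30, 50)
        ws = [kappa_to_width(k) for k in ks]
        assert np.all(np.diff(ws) < 0)

    def test_undefined_below_half_log2(self):
        with pytest.raises(ValueError):
            kappa_to_width(0.3)

    def test_rmax_closed_forms(self):
        assert rmax_from(1.0, 0.0) == pytest.approx(1.0)
        assert rmax_from(1.0, 1.0) == pytest.approx(np.e / ive(0, 1.0) / np.e)


class TestErrorDistribution:
    def test_uniform_in_zero_signal_limit(self):
        dist = nr_error_distribution(PopulationParams(1e-12, 4.0, 3), 1000, 0)
        np.testing.assert_allclose(dist.pmf, 1 / N_BINS)

    def test_pmf_normalized(self):
        dist = nr_error_distribution(PopulationParams(60.0, 4.0, 3), 20_000, 1)
        assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(dist.pmf >= 0)

    def test_matches_full_spiking_simulation(self):
        """Dense-tiling reduction agrees with the explicit M-neuron pipeline
        (mean rates -> Poisson spikes -> ML decode)."""
        p = PopulationParams(60.0, 4.0, 3, m_neurons=100)
        rng = np.random.default_rng(42)
        n_tr = 100_000
        rates = mean_rates(0.0, p)
        spikes = rng.poisson(rates, size=(n_tr, p.m_neurons))
        phi = p.preferred_values
        errors = np.arctan2(spikes @ np.sin(phi), spikes @ np.cos(phi))
        zero = spikes.sum(axis=1) == 0
        errors[zero] = rng.uniform(-np.pi, np.pi, zero.sum())
        hist = np.bincount(nearest_bin(errors), minlength=N_BINS) / n_tr
        dist = nr_error_distribution(p, 100_000, seed=7)
        assert 0.5 * np.abs(dist.pmf - hist).sum() < 0.01

    def test_set_size_identity(self):
        # amplitude is shared between items: (gamma, N=6) == (gamma/2, N=3)
        d6 = nr_error_distribution(PopulationParams(60.0, 4.0, 6), 20_000, 3)
        d3 = nr_error_distribution(PopulationParams(30.0, 4.0, 3), 20_000, 3)
        np.testing.assert_array_equal(d6.pmf, d3.pmf)

    def test_dispersion_monotone_in_gamma(self):
        sds = [nr_error_distribution(PopulationParams(g, 4.0, 3), 50_000, 5)
               .circular_sd() for g in (15.0, 40.0, 100.0)]
        assert sds[0] > sds[1] > sds[2]

    def test_long_tails_grow_with_kappa_at_matched_dispersion(self):
        """At matched circular SD, narrower tuning (higher kappa) produces
        more leptokurtic error distributions."""

        def matched_dist(kappa, target_sd=0.25):
            lo, hi = 1.0, 2000.0
            for _ in range(30):
                mid = np.sqrt(lo * hi)
                sd = nr_error_distribution(PopulationParams(mid, kappa, 3),
                                           30_000, 13).circular_sd()
                lo, hi = (lo, mid) if sd < target_sd else (mid, hi)
            return nr_error_distribution(PopulationParams(np.sqrt(lo * hi),
                                                          kappa, 3), 60_000, 13)

        def excess_kurtosis(dist):
            m2 = np.sum(dist.pmf * dist.bin_centers**2)
            m4 = np.sum(dist.pmf * dist.bin_centers**4)
            return m4 / m2**2 - 3.0

        assert (excess_kurtosis(matched_dist(8.0))
                > excess_kurtosis(matched_dist(2.0)))

    def test_decoder_unbiased(self):
        dist = nr_error_distribution(PopulationParams(60.0, 4.0, 3), 100_000, 9)
        resultant = np.sum(dist.pmf * np.exp(1j * dist.bin_centers))
        assert abs(np.angle(resultant)) < 0.02


class TestFitNeuralResource:
    def test_recovery_identifiable_structure(self):
        """The fit reaches the maximum-likelihood set: it never scores below
        the generating parameters, and reproduces the identifiable
        per-set-size error dispersion (the amplitude-width ridge leaves
        gamma and kappa themselves only jointly constrained)."""
        rng = np.random.default_rng(7)
        wm = simulate_nr_trials(60.0, 4.0, 200, rng)
        fit = fit_neural_resource(wm, seed=11)
        assert fit.converged
        # likelihood at the generating parameters, same evaluation scheme
        from simrecall.neural_resource import (_conditional_pmf_tables,
                                               _mixture_log_likelihood)
        ll_true = 0.0
        for n, g in wm.groupby("set_size"):
            lam = 60.0 / n
            counts = np.bincount(nearest_bin(g["error"].to_numpy()),
                                 minlength=N_BINS)
            tables = _conditional_pmf_tables(4.0, int(lam + 6 * np.sqrt(lam) + 10),
                                             20_000, 11)
            ll_true += _mixture_log_likelihood(counts, lam, tables)
        assert fit.log_likelihood >= ll_true - 1.0
        # identifiable functionals: predicted circular SD per set size
        for n, true_sd in ((3, 0.1238), (6, 0.1816)):
            got = nr_error_distribution(
                PopulationParams(fit.gamma, fit.kappa, n), 100_000, 5
            ).circular_sd()
            assert got == pytest.approx(true_sd, rel=0.12)
        assert fit.aic == pytest.approx(4 - 2 * fit.log_likelihood)

    def test_uniform_responses_drive_gamma_down(self):
        rng = np.random.default_rng(1)
        wm = pd.DataFrame({
            "set_size": np.repeat([3, 6], 150),
            "error": rng.uniform(-np.pi, np.pi, 300)})
        fit = fit_neural_resource(wm, seed=2)
        assert fit.gamma < 2.0

    def test_larger_set_size_widens_errors(self):
        d3 = nr_error_distribution(PopulationParams(60.0, 4.0, 3), 50_000, 1)
        d6 = nr_error_distribution(PopulationParams(60.0, 4.0, 6), 50_000, 1)
        assert d6.circular_sd() > d3.circular_sd()

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            fit_neural_resource(pd.DataFrame({"set_size": [3], "error": [0.1]}))
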