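"""Population-coding model of working-memory recall (neural resource model).

A remembered feature value theta is encoded by a homogeneous population
of M idealized neurons with von Mises tuning of concentration kappa,
whose preferred values evenly tile the circle.  The mean rate of neuron
i is

    r_i(theta) = gamma / (M * N) * exp(kappa * cos(theta - phi_i)) / I0(kappa),

where gamma is the total population activity and N the number of items
in memory (divisive normalization: activity is shared between items).
Spike counts are Poisson over a decoding window T, and the recall
estimate is the maximum-likelihood decode of the spike pattern.  Low
total activity produces heavy-tailed error distributions; gamma -> 0
recovers uniform guessing without a separate guess parameter.

For reporting, the model is reparameterized in terms of the peak rate
r_max = gamma * exp(kappa) / I0(kappa) and the tuning full-width at
half maximum W = 2 * arccos(1 + log(0.5) / kappa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ive

from . import _grid

__all__ = [
    "PopulationParams",
    "ErrorDistribution",
    "NRFit",
    "mean_rates",
    "sample_spikes",
    "ml_decode",
    "kappa_to_width",
    "width_to_kappa",
    "rmax_from",
    "nr_error_distribution",
    "fit_neural_resource",
]

KAPPA_WIDTH_MIN = np.log(2.0) / 2.0  # below this the tuning never falls to half peak
GAMMA_BOUNDS = (0.5, 2000.0)
KAPPA_BOUNDS = (0.05, 200.0)


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the idealized spiking population.

    gamma : total expected population spike count per decoding window
        (before division between the N memorized items).
    kappa : von Mises tuning concentration.
    n_items : set size N.
    m_neurons : simulation granularity M; predictions depend on M only
        through Monte-Carlo resolution.
    window : decoding interval T (fixed at 1; only gamma*T/N matters).
    """

    gamma: float
    kappa: float
    n_items: int = 1
    m_neurons: int = 100
    window: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.kappa < 0:
            raise ValueError("gamma and kappa must be non-negative")
        if self.n_items < 1 or self.m_neurons < 1:
            raise ValueError("n_items and m_neurons must be positive")

    @property
    def r_max(self) -> float:
        return rmax_from(self.gamma, self.kappa)

    @property
    def width(self) -> float:
        return kappa_to_width(self.kappa)

    @property
    def preferred_values(self) -> np.ndarray:
        return -np.pi + np.arange(self.m_neurons) * (2.0 * np.pi / self.m_neurons)


@dataclass(frozen=True)
class ErrorDistribution:
    """Probability mass over the 360 circular error bins."""

    bin_centers: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        if not np.isclose(self.pmf.sum(), 1.0, atol=1e-9):
            raise ValueError("pmf must sum to 1")
        if np.any(self.pmf < 0):
            raise ValueError("pmf entries must be non-negative")

    def log_prob(self, errors) -> np.ndarray:
        """Log probability of observed errors, linearly interpolated between bins."""
        errors = np.asarray(errors, dtype=float)
        # wrap-padded interpolation over the circular grid
        xs = np.concatenate([self.bin_centers, [self.bin_centers[0] + 2 * np.pi]])
        ys = np.concatenate([self.pmf, [self.pmf[0]]])
        p = np.interp(np.mod(errors + np.pi, 2 * np.pi) - np.pi, xs, ys)
        return np.log(np.maximum(p, 1e-300))

    def circular_sd(self) -> float:
        r = np.abs(np.sum(self.pmf * np.exp(1j * self.bin_centers)))
        return float(np.sqrt(-2.0 * np.log(max(r, 1e-300))))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.choice(len(self.pmf), size=n, p=self.pmf)
        return self.bin_centers[idx]


@dataclass(frozen=True)
class NRFit:
    """Per-observer maximum-likelihood fit of the population model."""

    r_max: float
    width: float
    gamma: float
    kappa: float
    log_likelihood: float
    aic: float
    converged: bool


def mean_rates(theta: float, params: PopulationParams) -> np.ndarray:
    """Expected firing rate of each neuron for stimulus value ``theta``.

    Computed as gamma/(M*N) * exp(kappa*(cos(theta - phi_i) - 1)) / ive(0, kappa),
    which is the exponentially scaled, overflow-safe form of the von
    Mises tuning curve.
    """
    phi = params.preferred_values
    k = params.kappa
    amp = params.gamma / (params.m_neurons * params.n_items)
    return amp * np.exp(k * (np.cos(theta - phi) - 1.0)) / ive(0, k)


def sample_spikes(rates, window: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson spike counts with means ``rates * window``."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    return rng.poisson(rates * window)


def ml_decode(counts, preferred_values, kappa: float,
              rng: np.random.Generator | None = None):
    """Maximum-likelihood stimulus estimate from a population spike pattern.

    For a uniform dense tiling of von Mises tuning curves the Poisson
    log likelihood is kappa * sum_i n_i cos(theta - phi_i) + const, so
    the ML estimate is the resultant (population-vector) direction and
    does not depend on kappa.  ``kappa`` is kept in the signature as
    part of the general (non-uniform tiling) contract.  A pattern with
    zero total spikes carries no information; a uniform random value is
    returned, flagged in the second return value.
    """
    counts = np.asarray(counts, dtype=float)
    preferred_values = np.asarray(preferred_values, dtype=float)
    if counts.shape != preferred_values.shape:
        raise ValueError("counts and preferred_values must have the same length")
    if counts.sum() == 0:
        if rng is None:
            rng = np.random.default_rng()
        return float(rng.uniform(-np.pi, np.pi)), True
    est = np.arctan2(counts @ np.sin(preferred_values),
                     counts @ np.cos(preferred_values))
    return float(est), False


def kappa_to_width(kappa: float) -> float:
    """Tuning full-width at half maximum, W = 2*arccos(1 + log(0.5)/kappa)."""
    if kappa < KAPPA_WIDTH_MIN:
        raise ValueError("tuning never falls to half its peak for kappa < ln(2)/2")
    return float(2.0 * np.arccos(1.0 + np.log(0.5) / kappa))


def width_to_kappa(width: float) -> float:
    """Exact inverse of :func:`kappa_to_width` for W in (0, 2*pi)."""
    if not 0.0 < width < 2.0 * np.pi:
        raise ValueError("width must lie in (0, 2*pi)")
    return float(np.log(2.0) / (1.0 - np.cos(width / 2.0)))


def rmax_from(gamma: float, kappa: float) -> float:
    """Peak firing rate r_max = gamma * exp(kappa) / I0(kappa)."""
    return float(gamma / ive(0, kappa))


def nr_error_distribution(
    params: PopulationParams,
    mc_samples: int = 50_000,
    seed: int | np.random.Generator = 0,
) -> ErrorDistribution:
    """Predicted recall-error distribution, tabulated by Monte Carlo.

    Uses the dense-tiling reduction of the spiking model: the total
    spike count is Poisson with mean gamma*T/N, and conditional on n
    spikes the decoding error is the resultant direction of n i.i.d.
    von Mises(0, kappa) spike positions.  The zero-spike (guessing)
    branch is folded in analytically as a uniform component, so the
    gamma -> 0 limit is exactly uniform.
    """
    lam = params.gamma * params.window / params.n_items
    pmf = np.zeros(_grid.N_BINS)
    p0 = np.exp(-lam)
    if lam > 0 and mc_samples > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        counts = rng.poisson(lam, mc_samples)
        counts = counts[counts > 0]
        if counts.size:
            draws = rng.vonmises(0.0, params.kappa, int(counts.sum()))
            stops = np.cumsum(counts)
            starts = np.concatenate([[0], stops[:-1]])
            s = np.add.reduceat(np.sin(draws), starts)
            c = np.add.reduceat(np.cos(draws), starts)
            errors = np.arctan2(s, c)
            hist = np.bincount(_grid.nearest_bin(errors), minlength=_grid.N_BINS)
            pmf = hist / hist.sum() * (1.0 - p0)
    pmf = pmf + p0 / _grid.N_BINS
    return ErrorDistribution(_grid.BIN_CENTERS.copy(), pmf / pmf.sum())


def _conditional_pmf_tables(kappa: float, n_max: int, mc: int,
                            seed: int) -> np.ndarray:
    """PMF of the decoding error conditional on each total spike count.

    Row n-1 (n = 1..n_max) tabulates, over the 360 bins, the error of the
    resultant direction of n i.i.d. von Mises(0, kappa) draws, estimated
    from ``mc`` Monte-Carlo samples per count via a single cumulative
    pass.  A small Laplace floor keeps log likelihoods finite in bins
    the samples missed.
    """
    rng = np.random.default_rng(seed)
    draws = rng.vonmises(0.0, kappa, (mc, n_max))
    cum_s = np.cumsum(np.sin(draws), axis=1)
    cum_c = np.cumsum(np.cos(draws), axis=1)
    bins = _grid.nearest_bin(np.arctan2(cum_s, cum_c))
    tables = np.empty((n_max, _grid.N_BINS))
    alpha = 0.25
    for n in range(n_max):
        hist = np.bincount(bins[:, n], minlength=_grid.N_BINS)
        tables[n] = (hist + alpha) / (mc + alpha * _grid.N_BINS)
    return tables


def _mixture_log_likelihood(counts: np.ndarray, lam: float,
                            tables: np.ndarray) -> float:
    """Log likelihood of binned errors under the Poisson(lam) count mixture.

    The zero-count branch contributes a uniform component; Poisson mass
    above the tabulated maximum count is lumped onto the last table row
    (the conditional error distribution changes negligibly there).
    """
    from scipy.stats import poisson

    n_max = tables.shape[0]
    w = poisson.pmf(np.arange(n_max + 1), lam)
    w[n_max] += max(1.0 - w.sum(), 0.0)
    mix = w[0] / _grid.N_BINS + w[1:] @ tables
    return float(counts @ np.log(mix))


def fit_neural_resource(
    wm_trials: pd.DataFrame,
    mc_samples: int = 5000,
    final_mc_samples: int = 20_000,
    seed: int = 12345,
    gamma_grid: np.ndarray | None = None,
    kappa_grid: np.ndarray | None = None,
    min_trials: int = 20,
) -> NRFit:
    """Joint ML fit of (gamma, kappa) to one observer's recall errors.

    ``wm_trials`` must carry columns ``error`` (analysis radians) and
    ``set_size``; gamma and kappa are shared across set sizes, with the
    1/N amplitude scaling supplied by the model.  The likelihood is
    evaluated from Monte-Carlo tables of the error distribution
    conditional on the total spike count (``mc_samples`` samples per
    count level, fixed seed: common random numbers), mixed with exact
    Poisson count weights — so the gamma dependence is noise-free and
    only kappa is tabulated stochastically.  A coarse (gamma, kappa)
    grid scan locates the global basin (the surface has a long flat
    ridge trading amplitude against tuning width), and a Nelder-Mead
    simplex polish refines it.  The reported log likelihood is
    re-evaluated with ``final_mc_samples`` samples per count level.
    """
    if len(wm_trials) < min_trials:
        raise ValueError(f"need at least {min_trials} trials")
    groups = {int(n): g["error"].to_numpy(dtype=float)
              for n, g in wm_trials.groupby("set_size")}
    counts = {n: np.bincount(_grid.nearest_bin(e), minlength=_grid.N_BINS)
              for n, e in groups.items()}
    min_items = min(groups)
    log_lo = np.log([GAMMA_BOUNDS[0], KAPPA_BOUNDS[0]])
    log_hi = np.log([GAMMA_BOUNDS[1], KAPPA_BOUNDS[1]])
    if gamma_grid is None:
        gamma_grid = np.geomspace(2.0, 400.0, 28)
    if kappa_grid is None:
        kappa_grid = np.geomspace(0.3, 24.0, 16)

    def n_max_for(lam: float) -> int:
        return int(lam + 6.0 * np.sqrt(lam) + 10)

    def ll_given_tables(gamma, tables):
        return sum(_mixture_log_likelihood(counts[n], gamma / n, tables)
                   for n in groups)

    # coarse scan: one table per kappa serves every gamma
    scan_nmax = n_max_for(gamma_grid.max() / min_items)
    row_best: list[tuple[float, float, float]] = []
    for kappa in kappa_grid:
        tables = _conditional_pmf_tables(kappa, scan_nmax, mc_samples, seed)
        lls = [ll_given_tables(gamma, tables) for gamma in gamma_grid]
        i = int(np.argmax(lls))
        row_best.append((lls[i], float(gamma_grid[i]), float(kappa)))

    def negll(params, mc):
        clipped = np.clip(params, log_lo, log_hi)
        penalty = 1e4 * np.sum((params - clipped) ** 2)
        gamma, kappa = np.exp(clipped)
        tables = _conditional_pmf_tables(
            kappa, n_max_for(gamma / min_items), mc, seed)
        return -ll_given_tables(gamma, tables) + penalty

    # the amplitude-width ridge is nearly flat, so Monte-Carlo noise can
    # shuffle the ranking of distant basins: polish the three best rows
    # separately and compare the polished candidates at high resolution
    candidates = []
    for _, g0, k0 in sorted(row_best, reverse=True)[:3]:
        res = minimize(lambda p: negll(p, mc_samples), np.log([g0, k0]),
                       method="Nelder-Mead",
                       options={"xatol": 5e-3, "fatol": 0.05, "maxiter": 100})
        candidates.append(res)
    scores = [negll(r.x, final_mc_samples) for r in candidates]
    best = candidates[int(np.argmin(scores))]
    gamma, kappa = np.exp(np.clip(best.x, log_lo, log_hi))
    ll = -min(scores)
    at_bound = bool(np.any(np.isclose(np.log([gamma, kappa]), log_lo, atol=1e-6))
                    or np.any(np.isclose(np.log([gamma, kappa]), log_hi, atol=1e-6)))
    return NRFit(
        r_max=rmax_from(gamma, kappa),
        width=kappa_to_width(kappa) if kappa >= KAPPA_WIDTH_MIN else float("nan"),
        gamma=float(gamma),
        kappa=float(kappa),
        log_likelihood=float(ll),
        aic=float(2 * 2 - 2 * ll),
        converged=bool(best.success) and not at_bound,
    )
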