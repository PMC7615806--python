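"""Target-confusability / signal-detection models of recall.

Recalling an item generates a noisy familiarity signal at each of 360
equally spaced candidate feature values.  The mean signal at offset
theta' from the target is d' * Omega(theta'), where Omega is a
responsiveness curve with unit peak, and each signal receives
independent unit-variance Gaussian noise.  The report is the candidate
with the strongest signal (max rule), plus a small fixed motor error
(wrapped normal, SD 2 deg on the analysis circle).

Three variants differ only in where Omega comes from:

- ``empirical``: the psychophysical similarity function measured in the
  quad task (one d' per set size, two free parameters).
- ``synthetic``: the same exponential-times-perceptual-noise family,
  but with the exponent fitted to the recall data (shared exponent plus
  one d' per set size, three free parameters).
- ``vonmises``: a unit-peak von Mises curve parameterized by circular
  SD, fitted to the recall data (three free parameters).

Fitting is grid search over the dense parameter grids (d' from 0 to 5.5
in steps of 0.02; exponent 0.001 to 10 in steps of 0.0313; circular SD
0.03 to 2 in steps of 0.0062).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ive, log_ndtr

from . import _grid
from .neural_resource import ErrorDistribution, PopulationParams
from .scaling import SimilarityFunction

__all__ = [
    "TCCParams",
    "TCCFit",
    "D_PRIME_GRID",
    "EXPONENT_GRID",
    "VM_SD_GRID",
    "vonmises_responsiveness",
    "kappa_from_circular_sd",
    "mean_signal",
    "report_pmf",
    "sample_reports",
    "fit_empirical_tcc",
    "fit_synthetic_tcc",
    "fit_vonmises_tcc",
    "nr_to_tcc_equivalent",
]

D_PRIME_GRID = np.round(np.arange(0.0, 5.5 + 1e-9, 0.02), 10)
EXPONENT_GRID = np.round(0.001 + 0.0313 * np.arange(320), 10)
VM_SD_GRID = np.round(0.03 + 0.0062 * np.arange(318), 10)

DEFAULT_MOTOR_SD_DEG = 2.0
# quadrature resolution: the max-rule integrand is smooth and rapidly
# decaying, so the trapezoid rule converges far below 1e-8 total variation
# already at a few hundred nodes (verified against a 10^4-node reference);
# the fit-time value keeps dense grid searches fast
QUAD_NODES_REPORT = 2000
QUAD_NODES_FIT = 220


@dataclass(frozen=True)
class TCCParams:
    """Parameters of one TCC variant."""

    variant: str  # empirical | synthetic | vonmises
    d_prime_by_setsize: dict[int, float]
    responsiveness: np.ndarray = field(repr=False)
    shape_param: float | None = None  # exponent (synthetic) or circular SD (vonmises)
    motor_sd_deg: float = DEFAULT_MOTOR_SD_DEG

    def __post_init__(self) -> None:
        if self.variant not in ("empirical", "synthetic", "vonmises"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for d in self.d_prime_by_setsize.values():
            if d < 0:
                raise ValueError("d' must be non-negative")
        if not np.isclose(self.responsiveness.max(), 1.0, atol=1e-6):
            raise ValueError("responsiveness must peak at 1")

    def error_distribution(self, set_size: int,
                           quad_nodes: int = QUAD_NODES_REPORT) -> ErrorDistribution:
        signal = mean_signal(self.responsiveness, self.d_prime_by_setsize[set_size])
        return report_pmf(signal, self.motor_sd_deg, quad_nodes=quad_nodes)


@dataclass(frozen=True)
class TCCFit:
    """Result of fitting one TCC variant to one observer."""

    params: TCCParams
    log_likelihood: float
    aic: float
    n_trials: int
    ll_by_setsize: dict[int, float]


def kappa_from_circular_sd(circ_sd: float) -> float:
    """Invert circular SD -> von Mises concentration.

    Circular SD s relates to the mean resultant length R = I1(k)/I0(k)
    through s = sqrt(-2 log R).
    """
    if circ_sd <= 0:
        raise ValueError("circular SD must be positive")
    target_r = np.exp(-0.5 * circ_sd**2)

    def f(log_k):
        k = np.exp(log_k)
        return ive(1, k) / ive(0, k) - target_r

    return float(np.exp(brentq(f, np.log(1e-6), np.log(1e7), xtol=1e-12)))


def vonmises_responsiveness(circ_sd: float) -> np.ndarray:
    """Unit-peak von Mises responsiveness curve on the standard grid."""
    kappa = kappa_from_circular_sd(circ_sd)
    return np.exp(kappa * (np.cos(_grid.BIN_CENTERS) - 1.0))


def responsiveness_from_similarity(omega) -> np.ndarray:
    """Responsiveness curve on the standard grid (unit peak).

    Accepts a :class:`~simrecall.scaling.SimilarityFunction` or a raw
    360-point array (e.g. a von Mises curve from the population-model
    mapping).
    """
    values = omega.values if isinstance(omega, SimilarityFunction) else np.asarray(omega, dtype=float)
    if len(values) != _grid.N_BINS:
        raise ValueError("responsiveness must be built on the 360-point grid")
    return values


def mean_signal(responsiveness: np.ndarray, d_prime: float) -> np.ndarray:
    """Mean familiarity signal d' * Omega at the 360 candidate values."""
    if d_prime < 0:
        raise ValueError("d' must be non-negative")
    return d_prime * np.asarray(responsiveness, dtype=float)


def _win_probabilities(signal: np.ndarray, quad_nodes: int) -> np.ndarray:
    """P(candidate i has the max signal) by quadrature over the shared noise axis.

    P(i wins) = int phi(x - m_i) prod_{j != i} Phi(x - m_j) dx.  Candidates
    sharing a mean signal are exchangeable, so the integral is evaluated
    once per unique mean value.
    """
    uniq, inv, cnt = np.unique(signal, return_inverse=True, return_counts=True)
    x = np.linspace(uniq.min() - 8.0, uniq.max() + 8.0, quad_nodes)
    a = log_ndtr(x[:, None] - uniq[None, :])  # log Phi per unique value
    s = a @ cnt  # log prod_j Phi(x - m_j)
    log_phi = -0.5 * (x[:, None] - uniq[None, :]) ** 2 - 0.5 * np.log(2 * np.pi)
    integrand = np.exp(s[:, None] - a + log_phi)
    p_u = np.trapezoid(integrand, x, axis=0)
    return p_u[inv]


def report_pmf(signal: np.ndarray, motor_sd_deg: float = DEFAULT_MOTOR_SD_DEG,
               quad_nodes: int = QUAD_NODES_REPORT) -> ErrorDistribution:
    """Distribution of reported error under the max rule plus motor noise.

    The motor SD is specified in degrees of the 360-point analysis
    circle (2 deg = 2 grid bins) for every feature dimension.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (_grid.N_BINS,):
        raise ValueError(f"signal must have length {_grid.N_BINS}")
    pmf = _win_probabilities(signal, quad_nodes)
    if motor_sd_deg > 0:
        kernel = _grid.wrapped_normal_kernel(np.deg2rad(motor_sd_deg))
        pmf = _grid.circular_convolve(pmf, kernel)
    pmf = np.maximum(pmf, 0.0)
    return ErrorDistribution(_grid.BIN_CENTERS.copy(), pmf / pmf.sum())


def sample_reports(signal: np.ndarray, motor_sd_deg: float, n: int,
                   rng: np.random.Generator, chunk: int = 20_000) -> np.ndarray:
    """Direct Monte-Carlo simulation of the max rule; returns errors in radians."""
    signal = np.asarray(signal, dtype=np.float32)
    out = np.empty(n)
    done = 0
    while done < n:
        m = min(chunk, n - done)
        noise = rng.standard_normal((m, signal.size), dtype=np.float32)
        idx = np.argmax(noise + signal, axis=1)
        out[done:done + m] = _grid.BIN_CENTERS[idx]
        done += m
    if motor_sd_deg > 0:
        out = out + rng.normal(0.0, np.deg2rad(motor_sd_deg), n)
    return np.mod(out + np.pi, 2 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# fitting


def _bin_counts(errors: np.ndarray) -> np.ndarray:
    return np.bincount(_grid.nearest_bin(errors), minlength=_grid.N_BINS)


def _ll_at(counts: np.ndarray, resp: np.ndarray, d: float,
           motor_kernel: np.ndarray | None, quad_nodes: int) -> float:
    pmf = _win_probabilities(d * resp, quad_nodes)
    if motor_kernel is not None:
        pmf = _grid.circular_convolve(pmf, motor_kernel)
    pmf = np.maximum(pmf / pmf.sum(), 1e-300)
    return float(counts @ np.log(pmf))


def _refine_argmax(evaluate, n_grid: int, coarse_stride: int,
                   cache: dict[int, float]) -> int:
    """Coarse-to-fine argmax over a 1-D grid of a smooth profile likelihood."""

    def ev(i):
        if i not in cache:
            cache[i] = evaluate(i)
        return cache[i]

    idx = list(range(0, n_grid, coarse_stride)) + [n_grid - 1]
    best = max(idx, key=ev)
    stride = coarse_stride
    while stride > 1:
        stride = max(stride // 4, 1)
        lo = max(best - 4 * stride, 0)
        hi = min(best + 4 * stride, n_grid - 1)
        best = max(range(lo, hi + 1, stride), key=ev)
    return best


def _search_d(counts, resp, motor_kernel, quad_nodes, d_grid,
              exhaustive: bool = False, hint: int | None = None):
    """Best d' on the grid for a fixed responsiveness curve.

    Returns (index, log likelihood).  With ``hint`` (a previous optimum)
    the search starts in a window around it and expands while the
    maximum sits on the window edge.
    """
    cache: dict[int, float] = {}

    def ev(i):
        if i not in cache:
            cache[i] = _ll_at(counts, resp, d_grid[i], motor_kernel, quad_nodes)
        return cache[i]

    n = len(d_grid)
    if exhaustive:
        best = max(range(n), key=ev)
        return best, cache[best]
    if hint is not None:
        lo, hi = max(hint - 8, 0), min(hint + 8, n - 1)
        while True:
            best = max(range(lo, hi + 1), key=ev)
            if best == lo and lo > 0:
                lo = max(lo - 16, 0)
            elif best == hi and hi < n - 1:
                hi = min(hi + 16, n - 1)
            else:
                break
        return best, cache[best]
    best = _refine_argmax(lambda i: _ll_at(counts, resp, d_grid[i],
                                           motor_kernel, quad_nodes),
                          n, 12, cache)
    return best, cache[best]


def _setsize_counts(wm_trials: pd.DataFrame) -> dict[int, np.ndarray]:
    return {int(n): _bin_counts(g["error"].to_numpy(dtype=float))
            for n, g in wm_trials.groupby("set_size")}


def _finalize(variant, counts_by_n, resp, best_idx_by_n, shape_param,
              motor_sd_deg, motor_kernel, d_grid, k_params, n_trials):
    d_by_n = {n: float(d_grid[i]) for n, i in best_idx_by_n.items()}
    ll_by_n = {n: _ll_at(counts_by_n[n], resp, d_by_n[n], motor_kernel,
                         QUAD_NODES_REPORT)
               for n in counts_by_n}
    ll = float(sum(ll_by_n.values()))
    params = TCCParams(variant, d_by_n, resp, shape_param, motor_sd_deg)
    return TCCFit(params, ll, 2.0 * k_params - 2.0 * ll, n_trials, ll_by_n)


def fit_empirical_tcc(
    wm_trials: pd.DataFrame,
    omega: SimilarityFunction,
    motor_sd_deg: float = DEFAULT_MOTOR_SD_DEG,
    d_grid: np.ndarray = D_PRIME_GRID,
    quad_nodes: int = QUAD_NODES_FIT,
    exhaustive: bool = False,
) -> TCCFit:
    """Fit d' per set size with the responsiveness curve fixed to the
    observer's measured similarity function (two free parameters)."""
    resp = responsiveness_from_similarity(omega)
    counts_by_n = _setsize_counts(wm_trials)
    if not counts_by_n:
        raise ValueError("no trials")
    kernel = (_grid.wrapped_normal_kernel(np.deg2rad(motor_sd_deg))
              if motor_sd_deg > 0 else None)
    best = {n: _search_d(c, resp, kernel, quad_nodes, d_grid,
                         exhaustive=exhaustive)[0]
            for n, c in counts_by_n.items()}
    return _finalize("empirical", counts_by_n, resp, best, None, motor_sd_deg,
                     kernel, d_grid, k_params=2, n_trials=int(len(wm_trials)))


def _fit_shape_variant(
    variant: str,
    wm_trials: pd.DataFrame,
    shape_grid: np.ndarray,
    resp_for,
    motor_sd_deg: float,
    d_grid: np.ndarray,
    quad_nodes: int,
    coarse_stride: int = 16,
) -> TCCFit:
    counts_by_n = _setsize_counts(wm_trials)
    if not counts_by_n:
        raise ValueError("no trials")
    kernel = (_grid.wrapped_normal_kernel(np.deg2rad(motor_sd_deg))
              if motor_sd_deg > 0 else None)
    hints: dict[int, int | None] = {n: None for n in counts_by_n}
    d_idx_cache: dict[int, dict[int, int]] = {}

    def joint_ll(i_shape: int) -> float:
        resp = resp_for(shape_grid[i_shape])
        total = 0.0
        d_idx_cache[i_shape] = {}
        for n, c in counts_by_n.items():
            i_d, ll = _search_d(c, resp, kernel, quad_nodes, d_grid,
                                hint=hints[n])
            hints[n] = i_d
            d_idx_cache[i_shape][n] = i_d
            total += ll
        return total

    best_shape = _refine_argmax(joint_ll, len(shape_grid), coarse_stride, {})
    resp = resp_for(shape_grid[best_shape])
    # re-search d' exhaustively in a generous window around the cached optimum
    best_d = {n: _search_d(c, resp, kernel, quad_nodes, d_grid,
                           hint=d_idx_cache[best_shape][n])[0]
              for n, c in counts_by_n.items()}
    return _finalize(variant, counts_by_n, resp, best_d,
                     float(shape_grid[best_shape]), motor_sd_deg, kernel,
                     d_grid, k_params=3, n_trials=int(len(wm_trials)))


def fit_synthetic_tcc(
    wm_trials: pd.DataFrame,
    perceptual_sd: float,
    motor_sd_deg: float = DEFAULT_MOTOR_SD_DEG,
    exponent_grid: np.ndarray = EXPONENT_GRID,
    d_grid: np.ndarray = D_PRIME_GRID,
    quad_nodes: int = QUAD_NODES_FIT,
) -> TCCFit:
    """Fit the exponential-family responsiveness curve to the recall data.

    One exponent is shared across set sizes, with a separate d' per set
    size (three free parameters); the exponent is searched on the dense
    grid, building each candidate curve by convolving the exponential
    with the feature's perceptual noise.
    """
    from .scaling import build_similarity_function

    def resp_for(exponent):
        return build_similarity_function(exponent, perceptual_sd).values

    return _fit_shape_variant("synthetic", wm_trials, exponent_grid, resp_for,
                              motor_sd_deg, d_grid, quad_nodes)


def fit_vonmises_tcc(
    wm_trials: pd.DataFrame,
    motor_sd_deg: float = DEFAULT_MOTOR_SD_DEG,
    sd_grid: np.ndarray = VM_SD_GRID,
    d_grid: np.ndarray = D_PRIME_GRID,
    quad_nodes: int = QUAD_NODES_FIT,
) -> TCCFit:
    """Fit the von Mises responsiveness variant (circular SD shared across
    set sizes, one d' per set size; three free parameters)."""
    return _fit_shape_variant("vonmises", wm_trials, sd_grid,
                              vonmises_responsiveness, motor_sd_deg, d_grid,
                              quad_nodes)


def nr_to_tcc_equivalent(
    params: PopulationParams,
    set_sizes: tuple[int, ...] = (3, 6),
    n_channels: int = _grid.N_BINS,
) -> TCCParams:
    """Gaussian-approximation mapping of population parameters into TCC.

    Approximating the Poisson channel noise as Gaussian with variance
    equal to the response amplitude xi = gamma / (n_channels * N), and
    rescaling signals by 1/sqrt(xi) to obtain unit variance, gives a
    signal-detection model with a unit-peak von Mises responsiveness of
    concentration kappa and peak signal strength

        d'_N = sqrt(gamma / (n_channels * N)) * exp(kappa) / I0(kappa).

    The sqrt gives the d'_3 / d'_6 = sqrt(2) set-size scaling.  The
    mapped model has no motor noise (the population model has none).
    """
    resp = np.exp(params.kappa * (np.cos(_grid.BIN_CENTERS) - 1.0))
    peak_gain = 1.0 / ive(0, params.kappa)  # e^kappa / I0(kappa)
    d_by_n = {int(n): float(np.sqrt(params.gamma / (n_channels * n)) * peak_gain)
              for n in set_sizes}
    circ_sd = float(np.sqrt(-2.0 * np.log(ive(1, params.kappa)
                                          / ive(0, params.kappa))))
    return TCCParams("vonmises", d_by_n, resp,
                     shape_param=circ_sd, motor_sd_deg=0.0)
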