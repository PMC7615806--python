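"""Parametric maximum-likelihood difference scaling (MLDS).

The quad task shows two pairs of stimuli and asks which pair is *less*
similar.  Perceived similarity is modelled as an exponential decay with
circular distance,

    omega(psi) = exp(-tau * psi),

convolved with a zero-mean wrapped normal of SD equal to the perceptual
noise measured in an undelayed reproduction task, then affinely rescaled
to [0, 1].  The decision model compares the similarities of the two
pairs corrupted by additive Gaussian noise of SD sigma; (tau, sigma) are
fit per observer by maximum likelihood.

The same curve family doubles as the responsiveness function of the
signal-detection recall models in :mod:`simrecall.tcc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from . import _grid
from .feature_space import FEATURE_SPACES, FeatureSpace, circ_dist, to_analysis_space

__all__ = [
    "SimilarityFunction",
    "MLDSFit",
    "PerceptualNoiseFit",
    "exponential_similarity",
    "build_similarity_function",
    "quad_choice_prob",
    "fit_mlds",
    "fit_perceptual_noise_sd",
]

TAU_MAX = 20.0
SIGMA_BOUNDS = (1e-3, 10.0)
MIN_QUAD_TRIALS = 50
RT_FILTER_MS = 200.0


@dataclass(frozen=True)
class SimilarityFunction:
    """Normalized psychophysical similarity curve on the circular grid.

    ``values[k]`` is the similarity at circular offset ``offsets[k]``;
    after normalization the peak value 1 is attained at offset 0 and the
    minimum 0 at +/-pi (unless the curve is degenerate, i.e. flat).
    """

    tau: float
    perceptual_sd: float
    offsets: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    norm_min: float
    norm_max: float
    degenerate: bool = False

    def __call__(self, psi):
        """Similarity at circular distance ``psi`` in [0, pi] (interpolated)."""
        psi = np.asarray(psi, dtype=float)
        if np.any(psi < -1e-12) or np.any(psi > np.pi + 1e-12):
            raise ValueError("distances must lie in [0, pi]; take circ_dist first")
        n = len(self.values)
        half = n // 2
        # offsets are -pi + k*step; index `half` is offset 0
        xs = np.concatenate([self.offsets[half:] - self.offsets[half], [np.pi]])
        ys = np.concatenate([self.values[half:], [self.values[0]]])
        return np.interp(np.clip(psi, 0.0, np.pi), xs, ys)


@dataclass(frozen=True)
class MLDSFit:
    """Per-observer MLDS estimate of (tau, sigma)."""

    tau: float
    sigma: float
    log_likelihood: float
    n_trials: int
    converged: bool


@dataclass(frozen=True)
class PerceptualNoiseFit:
    """Wrapped-normal SD fitted to pooled perceptual reproduction errors."""

    sd: float
    n_used: int
    n_excluded: int
    log_likelihood: float
    degenerate: bool = False
    at_bound: bool = False


def exponential_similarity(psi, tau: float):
    """Raw exponential similarity exp(-tau * psi) for psi in [0, pi]."""
    psi = np.asarray(psi, dtype=float)
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if np.any(psi < -1e-12) or np.any(psi > np.pi + 1e-12):
        raise ValueError("psi must be a circular distance in [0, pi]")
    return np.exp(-tau * psi)


def _grid_offsets(grid_n: int) -> np.ndarray:
    return -np.pi + np.arange(grid_n) * (2.0 * np.pi / grid_n)


def _log_ndtr_diff(hi, lo):
    # log(Phi(hi) - Phi(lo)) for hi >= lo, stable far in both tails:
    # mirror into the lower tail when the interval sits above zero
    from scipy.special import log_ndtr
    flip = (hi + lo) > 0
    h = np.where(flip, -lo, hi)
    l = np.where(flip, -hi, lo)
    a, b = log_ndtr(h), log_ndtr(l)
    return a + np.log1p(-np.exp(np.minimum(b - a, -1e-15)))


def convolved_similarity(x, tau: float, perceptual_sd: float) -> np.ndarray:
    """Circular convolution of exp(-tau*|.|) with a wrapped normal, exactly.

    Evaluates (omega (*) WN)(x) in closed form: each Gaussian image of
    the wrapped normal integrates against the two exponential branches
    of omega over one period, giving erf-type terms

        int_a^b e^{-s y} N(y; c, sd) dy
            = e^{s^2 sd^2/2 - s c} [Phi((b-c+s sd^2)/sd) - Phi((a-c+s sd^2)/sd)],

    summed (in log space, for overflow safety) over enough periodic
    images that the omitted wrapped-normal mass is below 1e-10.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    sd = perceptual_sd
    if sd == 0:
        return np.exp(-tau * np.abs(x))
    n_wraps = max(7, int(np.ceil(5.0 * sd / (2 * np.pi))) + 2)
    k = 2.0 * np.pi * np.arange(-n_wraps, n_wraps + 1)
    c = x[:, None] + k[None, :]
    out = np.zeros_like(c)
    pref = 0.5 * tau**2 * sd**2
    for s, a, b in ((-tau, -np.pi, 0.0), (tau, 0.0, np.pi)):
        log_mass = _log_ndtr_diff((b - c + s * sd**2) / sd,
                                  (a - c + s * sd**2) / sd)
        out += np.exp(pref - s * c + log_mass)
    return out.sum(axis=1)


def build_similarity_function(
    tau: float, perceptual_sd: float, grid_n: int = 360
) -> SimilarityFunction:
    """Exponential similarity convolved with perceptual noise, rescaled to [0, 1].

    The convolution with the wrapped-normal perceptual kernel is
    evaluated in closed form (see :func:`convolved_similarity`), so grid
    values carry no discretization error.  A flat curve (tau = 0)
    cannot be rescaled and is returned as all ones with the
    ``degenerate`` flag set.
    """
    if tau < 0 or perceptual_sd < 0:
        raise ValueError("tau and perceptual_sd must be non-negative")
    if grid_n < 8 or grid_n % 2:
        raise ValueError("grid_n must be an even number >= 8")
    offsets = _grid_offsets(grid_n)
    values = convolved_similarity(offsets, tau, perceptual_sd)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax - vmin < 1e-12:
        return SimilarityFunction(tau, perceptual_sd, offsets, np.ones(grid_n),
                                  vmin, vmax, degenerate=True)
    scaled = (values - vmin) / (vmax - vmin)
    return SimilarityFunction(tau, perceptual_sd, offsets, scaled, vmin, vmax)


def quad_choice_prob(omega: SimilarityFunction, psi_ab, psi_cd, sigma: float):
    """Probability that pair *ab* is judged less similar than pair *cd*.

    The pair with the smaller similarity has the larger perceived
    difference, so P(ab less similar) = Phi((Omega(psi_cd) -
    Omega(psi_ab)) / sigma).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return norm.cdf((omega(psi_cd) - omega(psi_ab)) / sigma)


def _quad_distances(trials: pd.DataFrame, space: FeatureSpace):
    ang = {c: to_analysis_space(trials[c].to_numpy(), space)
           for c in ("theta_a_deg", "theta_b_deg", "theta_c_deg", "theta_d_deg")}
    psi_ab = circ_dist(ang["theta_a_deg"], ang["theta_b_deg"])
    psi_cd = circ_dist(ang["theta_c_deg"], ang["theta_d_deg"])
    return psi_ab, psi_cd


def filter_quad_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop practice trials and trials with response time below 200 ms."""
    out = trials
    if "practice" in out.columns:
        out = out[out["practice"] == 0]
    if "rt_ms" in out.columns:
        out = out[out["rt_ms"] >= RT_FILTER_MS]
    return out


def fit_mlds(
    quad_trials: pd.DataFrame,
    perceptual_sd: float,
    space: FeatureSpace | None = None,
) -> MLDSFit:
    """Maximum-likelihood fit of (tau, sigma) to one observer's quad data.

    Practice trials and trials faster than 200 ms are excluded before
    fitting.  The Bernoulli likelihood of the observed choices is
    maximized over (log tau, log sigma) by Nelder-Mead simplex search
    from three starting points; the best run is returned.
    """
    if len(quad_trials) == 0:
        raise ValueError("empty trial table")
    if space is None:
        feat = quad_trials["feature"].iloc[0]
        space = FEATURE_SPACES[feat]
    trials = filter_quad_trials(quad_trials)
    if len(trials) < MIN_QUAD_TRIALS:
        raise ValueError(f"need at least {MIN_QUAD_TRIALS} analysable quad trials")
    psi_ab, psi_cd = _quad_distances(trials, space)
    y = (trials["choice"].to_numpy() == "ab").astype(float)

    # evaluate the convolved similarity at the exact trial distances,
    # normalizing with the true extrema Omega(0)=1, Omega(pi)=0
    eval_points = np.concatenate([[0.0, np.pi], psi_ab, psi_cd])
    n_t = len(psi_ab)

    log_bounds = (np.log([1e-4, SIGMA_BOUNDS[0]]), np.log([TAU_MAX, SIGMA_BOUNDS[1]]))

    def negll(params):
        lo, hi = log_bounds
        clipped = np.clip(params, lo, hi)
        penalty = 1e4 * np.sum((params - clipped) ** 2)
        tau, sigma = np.exp(clipped)
        v = convolved_similarity(eval_points, tau, perceptual_sd)
        span = v[0] - v[1]
        if span < 1e-12:
            p = np.full(n_t, 0.5)
        else:
            om = (v[2:] - v[1]) / span
            p = norm.cdf((om[n_t:] - om[:n_t]) / sigma)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -(y @ np.log(p) + (1 - y) @ np.log1p(-p)) + penalty

    starts = [(0.5, 0.2), (1.5, 0.2), (3.0, 0.4)]
    best = None
    for tau0, sigma0 in starts:
        res = minimize(negll, np.log([tau0, sigma0]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 800})
        if best is None or res.fun < best.fun:
            best = res
    tau, sigma = np.exp(np.clip(best.x, *log_bounds))
    at_bound = bool(
        tau >= TAU_MAX * 0.999
        or sigma <= SIGMA_BOUNDS[0] * 1.001
        or sigma >= SIGMA_BOUNDS[1] * 0.999
    )
    degenerate_data = bool(np.all(y == y[0]))
    return MLDSFit(
        tau=float(tau),
        sigma=float(sigma),
        log_likelihood=float(-best.fun),
        n_trials=len(trials),
        converged=bool(best.success) and not at_bound and not degenerate_data,
    )


def fit_perceptual_noise_sd(
    perceptual_errors,
    sd_upper: float = 2.0,
    min_errors: int = 20,
) -> PerceptualNoiseFit:
    """ML fit of a zero-mean wrapped normal SD to pooled reproduction errors.

    Errors more than 3 SD from the mean are excluded in a single pass
    before fitting.  Data inconsistent with a wrapped normal (e.g.
    uniform) drive the estimate to ``sd_upper``, which is flagged.
    """
    errors = np.asarray(perceptual_errors, dtype=float)
    if len(errors) < min_errors:
        raise ValueError(f"need at least {min_errors} errors")
    mu, sd = errors.mean(), errors.std()
    if sd > 0:
        keep = np.abs(errors - mu) <= 3.0 * sd
    else:
        keep = np.ones(len(errors), dtype=bool)
    kept = errors[keep]
    if np.all(kept == 0):
        return PerceptualNoiseFit(0.0, len(kept), int((~keep).sum()), np.inf,
                                  degenerate=True)

    def negll(log_sd):
        return -np.sum(np.log(_grid.wrapped_normal_pdf(kept, np.exp(log_sd)) + 1e-300))

    res = minimize_scalar(negll, bounds=(np.log(1e-3), np.log(sd_upper)),
                          method="bounded", options={"xatol": 1e-8})
    sd_hat = float(np.exp(res.x))
    return PerceptualNoiseFit(
        sd=sd_hat,
        n_used=len(kept),
        n_excluded=int((~keep).sum()),
        log_likelihood=float(-res.fun),
        at_bound=bool(sd_hat >= sd_upper * 0.995),
    )
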