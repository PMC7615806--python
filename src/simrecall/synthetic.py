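"""Synthetic observer cohorts for the three behavioral tasks.

Generates complete studies — quad similarity judgments, perceptual
analogue report, and working-memory analogue report — from known
per-observer latent parameters, so that every stage of the analysis
pipeline can be exercised and validated by parameter recovery.

Per observer, latent parameters (tau, sigma) of the similarity/decision
model and (gamma, kappa) of the recall model are drawn from log-normal
distributions; a Gaussian copula couples the quad decision noise sigma
to the memory amplitude gamma, emulating a shared source of variability
across tasks (observers who judge similarity noisily also recall less
precisely).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import tcc
from .feature_space import (FEATURE_SPACES, FeatureSpace, circ_dist,
                            from_analysis_space, to_analysis_space)
from .neural_resource import PopulationParams
from .scaling import build_similarity_function, quad_choice_prob

__all__ = [
    "StudyConfig",
    "DEFAULT_PERCEPTUAL_SD",
    "sample_quad_stimuli",
    "generate_study",
]

# per-feature study sizes (observers; analysed quad trials)
DEFAULT_N_OBSERVERS = {"color": 90, "orientation": 100, "location": 104, "shape": 102}
DEFAULT_N_QUAD = {"color": 210, "orientation": 230, "location": 240, "shape": 240}
# perceptual-noise SDs (analysis radians) of the four feature dimensions
DEFAULT_PERCEPTUAL_SD = {"color": 0.103, "orientation": 0.147,
                         "location": 0.022, "shape": 0.137}

N_PRACTICE_QUAD = 9
N_PRACTICE_WM = 15
N_PRACTICE_PERCEPTUAL = 10


@dataclass(frozen=True)
class StudyConfig:
    """Design and latent-parameter distributions of one synthetic study."""

    feature: str = "color"
    n_observers: int | None = None
    n_quad_trials: int | None = None
    n_wm_trials: int = 100
    n_perceptual_trials: int = 50
    set_sizes: tuple[int, ...] = (3, 6)
    perceptual_sd: float | None = None
    # latent log-normal distributions: (median, sd of log)
    tau_dist: tuple[float, float] = (1.5, 0.35)
    sigma_dist: tuple[float, float] = (0.15, 0.35)
    gamma_dist: tuple[float, float] = (60.0, 0.35)
    kappa_dist: tuple[float, float] = (4.0, 0.25)
    coupling: float = -0.6  # corr(latent sigma, latent gamma) via Gaussian copula
    wm_generator: str = "nr"  # "nr" (Poisson population) or "tcc_vonmises"
    strict_disjoint_arcs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_SPACES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if not -1 < self.coupling < 1:
            raise ValueError("|coupling| must be < 1")
        if self.wm_generator not in ("nr", "tcc_vonmises"):
            raise ValueError("wm_generator must be 'nr' or 'tcc_vonmises'")
        if self.n_observers is None:
            object.__setattr__(self, "n_observers",
                               DEFAULT_N_OBSERVERS[self.feature])
        if self.n_quad_trials is None:
            object.__setattr__(self, "n_quad_trials",
                               DEFAULT_N_QUAD[self.feature])
        if self.perceptual_sd is None:
            object.__setattr__(self, "perceptual_sd",
                               DEFAULT_PERCEPTUAL_SD[self.feature])

    @property
    def space(self) -> FeatureSpace:
        return FEATURE_SPACES[self.feature]


def _arc_members(i: int, j: int, n: int) -> set[int]:
    """Grid indices on the shorter arc from i to j (inclusive); ties (exactly
    opposite points) resolve to the arc running forward from i."""
    d = (j - i) % n
    if d <= n - d:
        return {(i + k) % n for k in range(d + 1)}
    return {(j + k) % n for k in range((n - d) + 1)}


def sample_quad_stimuli(space: FeatureSpace, rng: np.random.Generator,
                        strict: bool = True, max_attempts: int = 10_000
                        ) -> tuple[float, float, float, float]:
    """Four quad-task stimulus values (native degrees) on the 72-point grid.

    The first pair is sampled without replacement (its signed circular
    distance never exceeds half the native period).  The second pair is
    sampled by rejection from the remainder of the space so that the
    shorter arcs spanned by the two pairs are disjoint; with
    ``strict=False`` only distinct endpoints are enforced.
    """
    n = space.n_quad_values
    grid = space.grid_deg
    i1, i2 = rng.choice(n, size=2, replace=False)
    arc1 = _arc_members(int(i1), int(i2), n)
    if not strict:
        pool = [k for k in range(n) if k not in (i1, i2)]
        i3, i4 = rng.choice(pool, size=2, replace=False)
        return grid[i1], grid[i2], grid[i3], grid[i4]
    pool = [k for k in range(n) if k not in arc1]
    for _ in range(max_attempts):
        if len(pool) < 2:
            break
        i3, i4 = rng.choice(pool, size=2, replace=False)
        if _arc_members(int(i3), int(i4), n).isdisjoint(arc1):
            return grid[i1], grid[i2], grid[i3], grid[i4]
    raise RuntimeError("could not sample disjoint quad arcs")


def _draw_latents(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_observers
    z = rng.standard_normal((n, 4))  # tau, sigma, gamma, kappa
    # couple sigma and gamma through a Gaussian copula
    rho = config.coupling
    z_gamma = rho * z[:, 1] + np.sqrt(1 - rho**2) * z[:, 2]
    def ln(dist, zz):
        median, sdlog = dist
        return np.exp(np.log(median) + sdlog * zz)
    latents = pd.DataFrame({
        "observer_id": [f"obs{i:03d}" for i in range(n)],
        "tau": ln(config.tau_dist, z[:, 0]),
        "sigma": ln(config.sigma_dist, z[:, 1]),
        "gamma": ln(config.gamma_dist, z_gamma),
        "kappa": ln(config.kappa_dist, z[:, 3]),
    })
    # equivalent signal-detection amplitudes per set size (Gaussian mapping)
    d3, d6 = [], []
    for g, k in zip(latents["gamma"], latents["kappa"]):
        mapped = tcc.nr_to_tcc_equivalent(PopulationParams(g, k, 1))
        d3.append(mapped.d_prime_by_setsize[3])
        d6.append(mapped.d_prime_by_setsize[6])
    latents["d3"], latents["d6"] = d3, d6
    return latents


def _sample_nr_errors(gamma: float, kappa: float, n_items: int, n_trials: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Recall errors from the spiking model via the dense-tiling reduction."""
    lam = gamma / n_items
    counts = rng.poisson(lam, n_trials)
    errors = rng.uniform(-np.pi, np.pi, n_trials)
    pos = counts > 0
    if pos.any():
        draws = rng.vonmises(0.0, kappa, int(counts[pos].sum()))
        stops = np.cumsum(counts[pos])
        starts = np.concatenate([[0], stops[:-1]])
        errors[pos] = np.arctan2(np.add.reduceat(np.sin(draws), starts),
                                 np.add.reduceat(np.cos(draws), starts))
    return errors


def _simulate_quad(config, latents, rng) -> pd.DataFrame:
    space = config.space
    rows = []
    n_total = N_PRACTICE_QUAD + config.n_quad_trials
    for _, obs in latents.iterrows():
        omega = build_similarity_function(obs["tau"], config.perceptual_sd)
        th = np.array([sample_quad_stimuli(space, rng,
                                           strict=config.strict_disjoint_arcs)
                       for _ in range(n_total)])
        psi_ab = circ_dist(to_analysis_space(th[:, 0], space),
                           to_analysis_space(th[:, 1], space))
        psi_cd = circ_dist(to_analysis_space(th[:, 2], space),
                           to_analysis_space(th[:, 3], space))
        p_ab = quad_choice_prob(omega, psi_ab, psi_cd, obs["sigma"])
        choice = np.where(rng.uniform(size=n_total) < p_ab, "ab", "cd")
        rt = np.exp(rng.normal(np.log(900.0), 0.5, n_total))
        rows.append(pd.DataFrame({
            "observer_id": obs["observer_id"],
            "feature": config.feature,
            "theta_a_deg": th[:, 0], "theta_b_deg": th[:, 1],
            "theta_c_deg": th[:, 2], "theta_d_deg": th[:, 3],
            "choice": choice,
            "rt_ms": rt,
            "practice": (np.arange(n_total) < N_PRACTICE_QUAD).astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


def _simulate_wm(config, latents, rng) -> pd.DataFrame:
    space = config.space
    rows = []
    n_total = N_PRACTICE_WM + config.n_wm_trials
    for _, obs in latents.iterrows():
        # set sizes interleaved 50/50
        set_size = np.tile(config.set_sizes,
                           n_total // len(config.set_sizes) + 1)[:n_total]
        set_size = rng.permutation(set_size)
        target = rng.uniform(0.0, space.native_period, n_total)
        errors = np.empty(n_total)
        for n_items in config.set_sizes:
            sel = set_size == n_items
            if config.wm_generator == "nr":
                errors[sel] = _sample_nr_errors(obs["gamma"], obs["kappa"],
                                                n_items, int(sel.sum()), rng)
            else:
                resp = tcc.vonmises_responsiveness(_circ_sd_of_kappa(obs["kappa"]))
                d = obs["d3"] if n_items == 3 else obs["d6"]
                errors[sel] = tcc.sample_reports(d * resp,
                                                 tcc.DEFAULT_MOTOR_SD_DEG,
                                                 int(sel.sum()), rng)
        target_rad = np.deg2rad(target * space.doubling_factor)
        response_rad = target_rad + errors
        response = from_analysis_space(
            np.mod(response_rad + np.pi, 2 * np.pi) - np.pi, space)
        rows.append(pd.DataFrame({
            "observer_id": obs["observer_id"],
            "feature": config.feature,
            "set_size": set_size,
            "target_deg": target,
            "response_deg": response,
            "practice": (np.arange(n_total) < N_PRACTICE_WM).astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


def _circ_sd_of_kappa(kappa: float) -> float:
    from scipy.special import ive
    return float(np.sqrt(-2.0 * np.log(ive(1, kappa) / ive(0, kappa))))


def _simulate_perceptual(config, latents, rng) -> pd.DataFrame:
    space = config.space
    rows = []
    n_total = N_PRACTICE_PERCEPTUAL + config.n_perceptual_trials
    for _, obs in latents.iterrows():
        target = rng.uniform(0.0, space.native_period, n_total)
        errors = rng.normal(0.0, config.perceptual_sd, n_total)
        target_rad = np.deg2rad(target * space.doubling_factor)
        response = from_analysis_space(
            np.mod(target_rad + errors + np.pi, 2 * np.pi) - np.pi, space)
        rows.append(pd.DataFrame({
            "observer_id": obs["observer_id"],
            "feature": config.feature,
            "target_deg": target,
            "response_deg": response,
            "practice": (np.arange(n_total) < N_PRACTICE_PERCEPTUAL).astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


def generate_study(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Simulate a complete study; returns quad, wm, perceptual and latent tables.

    Fully reproducible from ``config.seed``; the practice trials that
    the analysis excludes are included and flagged.
    """
    rng = np.random.default_rng(config.seed)
    latents = _draw_latents(config, rng)
    return {
        "latents": latents,
        "quad": _simulate_quad(config, latents, rng),
        "wm": _simulate_wm(config, latents, rng),
        "perceptual": _simulate_perceptual(config, latents, rng),
    }
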