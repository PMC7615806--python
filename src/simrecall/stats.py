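"""Group-level statistics: AIC comparison, outlier handling, pooling,
correlations, attenuation correction and bootstrap reliability.

Correlations between per-observer model parameters are computed after
iteratively excluding values more than 3 SD from the mean; when data
from several feature dimensions are pooled, each feature is
standardized (after its own outlier pass) before concatenation.
Observed correlations are corrected for measurement unreliability with
the classical attenuation formula r' = r / sqrt(r_xx * r_yy), the
reliabilities being estimated by a split-resample bootstrap of the
trial-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationReport",
    "aic",
    "delta_aic",
    "iterative_outlier_mask",
    "standardize_and_pool",
    "pearson_r",
    "partial_r",
    "attenuation_correct",
    "corrected_correlation",
    "bootstrap_reliability",
]


@dataclass(frozen=True)
class CorrelationReport:
    """A Pearson (or partial) correlation with optional attenuation correction."""

    r: float
    n: int
    r_corrected: float | None = None
    reliability_x: float | None = None
    reliability_y: float | None = None
    partial_out: str | None = None
    corrected_out_of_range: bool = False


def aic(log_likelihood: float, k_params: int) -> float:
    """Akaike information criterion, 2k - 2 log L."""
    if k_params < 0:
        raise ValueError("k_params must be non-negative")
    return 2.0 * k_params - 2.0 * log_likelihood


def delta_aic(aic_a, aic_b) -> float:
    """Mean per-observer AIC(A) - AIC(B); positive favors model B."""
    return float(np.mean(np.asarray(aic_a) - np.asarray(aic_b)))


def iterative_outlier_mask(values, n_sd: float = 3.0) -> np.ndarray:
    """Boolean inclusion mask after iterative +/- n_sd exclusion.

    Mean and SD are recomputed on the surviving values and the exclusion
    repeated until no value lies beyond ``n_sd`` SDs; identical values
    (SD = 0) are never removed.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 values")
    mask = np.isfinite(values)
    while True:
        kept = values[mask]
        sd = kept.std()
        if sd == 0:
            break
        new_mask = mask & (np.abs(values - kept.mean()) <= n_sd * sd)
        if new_mask.sum() == mask.sum():
            break
        mask = new_mask
    return mask


def standardize_and_pool(per_feature_vectors: dict[str, np.ndarray],
                         min_survivors: int = 3) -> np.ndarray:
    """Z-score each feature's values after outlier removal, then concatenate.

    Features with fewer than ``min_survivors`` surviving values are
    dropped (with a warning) rather than contributing unstable z-scores.
    """
    import warnings

    blocks = []
    for name, vec in per_feature_vectors.items():
        vec = np.asarray(vec, dtype=float)
        mask = iterative_outlier_mask(vec)
        kept = vec[mask]
        if len(kept) < min_survivors:
            warnings.warn(f"feature {name!r} dropped: too few values after "
                          "outlier removal")
            continue
        blocks.append((kept - kept.mean()) / kept.std())
    if not blocks:
        raise ValueError("no feature survived pooling")
    return np.concatenate(blocks)


def _joint_mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # a point is removed if it is outlying on either variable
    return iterative_outlier_mask(x) & iterative_outlier_mask(y)


def pearson_r(x, y, remove_outliers: bool = True) -> CorrelationReport:
    """Pearson correlation after (optional) joint +/-3 SD outlier removal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if remove_outliers:
        mask = _joint_mask(x, y)
        x, y = x[mask], y[mask]
    if len(x) < 4:
        raise ValueError("need at least 4 paired values")
    r = float(sps.pearsonr(x, y).statistic)
    return CorrelationReport(r=r, n=len(x))


def partial_r(x, y, z, remove_outliers: bool = True,
              covariate_name: str = "z") -> CorrelationReport:
    """First-order partial correlation of x and y controlling for z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not len(x) == len(y) == len(z):
        raise ValueError("x, y, z must be paired")
    if remove_outliers:
        mask = _joint_mask(x, y) & iterative_outlier_mask(z)
        x, y, z = x[mask], y[mask], z[mask]
    if len(x) < 4:
        raise ValueError("need at least 4 paired values")
    rxy = sps.pearsonr(x, y).statistic
    rxz = sps.pearsonr(x, z).statistic
    ryz = sps.pearsonr(y, z).statistic
    r = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    return CorrelationReport(r=float(r), n=len(x), partial_out=covariate_name)


def attenuation_correct(r_xy: float, r_xx: float, r_yy: float) -> float:
    """Correction for attenuation, r' = r_xy / sqrt(r_xx * r_yy).

    ``r_xx`` and ``r_yy`` are the reliabilities of the two measures; the
    corrected magnitude is never smaller than the observed one and may
    exceed 1 (callers flag rather than clip).
    """
    if r_xx <= 0 or r_yy <= 0:
        raise ValueError("reliabilities must be positive")
    return float(r_xy / np.sqrt(r_xx * r_yy))


def corrected_correlation(r_xy: float, r_xx: float, r_yy: float,
                          n: int) -> CorrelationReport:
    """Bundle an observed correlation with its attenuation-corrected value."""
    rc = attenuation_correct(r_xy, r_xx, r_yy)
    return CorrelationReport(r=r_xy, n=n, r_corrected=rc,
                             reliability_x=r_xx, reliability_y=r_yy,
                             corrected_out_of_range=bool(abs(rc) > 1))


def bootstrap_reliability(
    trials: dict,
    fit_fn,
    n_replicates: int = 100,
    seed: int | np.random.Generator = 0,
) -> float:
    """Split-resample bootstrap estimate of a fitted parameter's reliability.

    For each replicate, every observer's trials are resampled with
    replacement twice and ``fit_fn`` applied to both resamples; the two
    resulting per-observer estimate vectors are correlated (after
    +/-3 SD exclusion) and the reliability is the mean correlation over
    replicates.  Replicates where the fitter fails are skipped.

    ``trials`` maps observer id -> an indexable table (DataFrame or
    array) of that observer's trials; ``fit_fn(resampled_table)`` must
    return a scalar estimate.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    obs_ids = list(trials)
    corrs = []
    for _ in range(n_replicates):
        a, b = [], []
        failed = False
        for oid in obs_ids:
            tbl = trials[oid]
            n = len(tbl)
            try:
                for dest in (a, b):
                    idx = rng.integers(0, n, n)
                    resampled = (tbl.iloc[idx] if hasattr(tbl, "iloc")
                                 else np.asarray(tbl)[idx])
                    dest.append(float(fit_fn(resampled)))
            except Exception:
                failed = True
                break
        if failed:
            continue
        try:
            corrs.append(pearson_r(np.array(a), np.array(b)).r)
        except ValueError:
            continue
    if not corrs:
        raise RuntimeError("all bootstrap replicates failed")
    return float(np.mean(corrs))
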