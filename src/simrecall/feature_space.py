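"""Circular feature spaces and circular arithmetic.

Four visual feature dimensions are modelled, each forming a continuous
circular space: color (hue wheel), orientation, angular location, and an
artificial shape wheel.  Orientation is unique over a half circle
(native period 180 deg) and is doubled before analysis so that every
space maps onto the same analysis convention: radians in [-pi, pi).

All model code works in analysis radians; degrees appear only at I/O
boundaries (CSV trial tables).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureSpace",
    "FEATURE_SPACES",
    "wrap_angle",
    "to_analysis_space",
    "from_analysis_space",
    "circ_diff",
    "circ_dist",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class FeatureSpace:
    """A circular stimulus dimension.

    Parameters
    ----------
    name : str
        One of ``color``, ``orientation``, ``location``, ``shape``.
    native_period : float
        Period of the physical space in degrees (180 for orientation,
        360 otherwise).
    doubling_factor : int
        Multiplier applied before conversion to analysis radians
        (2 for orientation, 1 otherwise).
    quad_step : float
        Discretization step (degrees) used when sampling quad-task
        stimuli; 72 unique values in every space.
    """

    name: str
    native_period: float
    doubling_factor: int
    quad_step: float
    n_quad_values: int = 72

    def __post_init__(self) -> None:
        if not np.isclose(self.native_period * self.doubling_factor, 360.0):
            raise ValueError("native_period x doubling_factor must equal 360")
        if not np.isclose(self.quad_step * self.n_quad_values, self.native_period):
            raise ValueError("quad_step x n_quad_values must equal native_period")

    @property
    def grid_deg(self) -> np.ndarray:
        """The discretized quad-task stimulus values in native degrees."""
        return np.arange(self.n_quad_values) * self.quad_step


FEATURE_SPACES: dict[str, FeatureSpace] = {
    "color": FeatureSpace("color", 360.0, 1, 5.0),
    "orientation": FeatureSpace("orientation", 180.0, 2, 2.5),
    "location": FeatureSpace("location", 360.0, 1, 5.0),
    "shape": FeatureSpace("shape", 360.0, 1, 5.0),
}


def wrap_angle(theta):
    """Wrap angles (radians) to [-pi, pi); exactly +pi maps to -pi."""
    return np.mod(np.asarray(theta, dtype=float) + np.pi, TWO_PI) - np.pi


def to_analysis_space(value_deg, space: FeatureSpace):
    """Convert native degrees to analysis radians in [-pi, pi).

    The value is multiplied by the space's doubling factor (2 for
    orientation, so the half-circle orientation space fills the full
    analysis circle) and converted to radians.
    """
    value_deg = np.asarray(value_deg, dtype=float)
    if not np.all(np.isfinite(value_deg)):
        raise ValueError("non-finite stimulus value in trial record")
    return wrap_angle(np.deg2rad(value_deg * space.doubling_factor))


def from_analysis_space(theta, space: FeatureSpace):
    """Inverse of :func:`to_analysis_space`, modulo the native period."""
    theta = np.asarray(theta, dtype=float)
    deg = np.rad2deg(theta) / space.doubling_factor
    return np.mod(deg, space.native_period)


def circ_diff(a, b):
    """Signed circular difference a - b, wrapped to [-pi, pi)."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circ_dist(a, b):
    """Absolute circular distance |a - b| in [0, pi]."""
    return np.abs(circ_diff(a, b))
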