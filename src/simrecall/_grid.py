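"""Shared 360-point circular grid used by all error-distribution code.

Responsiveness functions, predicted error distributions and observed
errors are all tabulated at 360 equally spaced points of the analysis
circle, with bin centers at -pi + k * (2*pi/360), so that 0 and -pi are
grid points.
"""

from __future__ import annotations

import numpy as np

N_BINS = 360
BIN_WIDTH = 2.0 * np.pi / N_BINS
BIN_CENTERS = -np.pi + np.arange(N_BINS) * BIN_WIDTH

# index matrix for direct circular convolution: _CONV_IDX[i, j] = (i - j) mod N
_CONV_IDX = (np.arange(N_BINS)[:, None] - np.arange(N_BINS)[None, :]) % N_BINS


def wrapped_normal_pdf(x, sd: float, n_wraps: int = 7) -> np.ndarray:
    """Density of a zero-mean wrapped normal at angles ``x`` (radians).

    The normal density is summed over ``2*n_wraps + 1`` periods; for
    sd <= 2 the omitted mass is far below 1e-10.
    """
    x = np.asarray(x, dtype=float)
    if sd <= 0:
        raise ValueError("sd must be positive")
    k = np.arange(-n_wraps, n_wraps + 1)
    z = (x[..., None] + 2.0 * np.pi * k) / sd
    return np.sum(np.exp(-0.5 * z * z), axis=-1) / (sd * np.sqrt(2.0 * np.pi))


def wrapped_normal_kernel(sd: float, n_wraps: int = 7) -> np.ndarray:
    """Discrete wrapped-normal smoothing kernel on the standard grid.

    Normalized to sum to one; ``sd`` in analysis radians.  ``sd = 0``
    returns the identity kernel.
    """
    if sd == 0:
        kernel = np.zeros(N_BINS)
        kernel[0] = 1.0
        return kernel
    offsets = wrap_angle_grid()
    kernel = wrapped_normal_pdf(offsets, sd, n_wraps=n_wraps)
    return kernel / kernel.sum()


def wrap_angle_grid() -> np.ndarray:
    """Grid offsets reordered so index 0 is offset 0 (kernel convention)."""
    return np.minimum.reduce([np.abs(np.arange(N_BINS)),
                              np.abs(np.arange(N_BINS) - N_BINS)]) * BIN_WIDTH


def circular_convolve(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct-summation circular convolution on the standard grid.

    ``kernel`` is indexed by lag (index 0 = zero lag) and should sum to
    one for a smoothing operation.
    """
    return kernel[_CONV_IDX] @ values


def nearest_bin(errors) -> np.ndarray:
    """Index of the nearest grid bin center for errors in [-pi, pi)."""
    errors = np.asarray(errors, dtype=float)
    return np.round((errors + np.pi) / BIN_WIDTH).astype(int) % N_BINS
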