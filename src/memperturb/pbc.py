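"""Minimum-image helpers for orthorhombic periodic boxes."""

from __future__ import annotations

import numpy as np


def min_image_vectors(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement vectors b - a, broadcasting numpy-style.

    *box* is the (3,) vector of orthorhombic box lengths (nm).
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - np.asarray(box) * np.round(d / np.asarray(box))


def min_image_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances, shape (len(a), len(b))."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    d = min_image_vectors(a[:, None, :], b[None, :, :], box)
    return np.linalg.norm(d, axis=-1)


def min_image_scalar(da: np.ndarray, length: float) -> np.ndarray:
    """Minimum-image convention applied to 1-D separations."""
    return da - length * np.round(np.asarray(da, dtype=float) / length)


def wrap_positions(xyz: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, box) per axis."""
    return np.mod(xyz, np.asarray(box))


def unwrap_series(z: np.ndarray, length: float | np.ndarray) -> np.ndarray:
    """Unwrap a 1-D coordinate series by accumulating minimum-image steps.

    *length* may be a scalar or a per-frame array of box lengths.
    """
    z = np.asarray(z, dtype=float)
    steps = np.diff(z)
    L = np.asarray(length, dtype=float)
    L_step = L if L.ndim == 0 else L[1:]
    steps = steps - L_step * np.round(steps / L_step)
    out = np.empty_like(z)
    out[0] = z[0]
    out[1:] = z[0] + np.cumsum(steps)
    return out
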