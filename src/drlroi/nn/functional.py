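"""Stateless array functions shared by the layer modules."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis``."""
    shifted = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


def log_softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return x - logsumexp(x, axis=axis, keepdims=True)


def bilinear_upsample(grid: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Bilinearly resample a 2-D ``grid`` onto ``shape`` (align-corners).

    Output pixel (i, j) samples the grid at continuous coordinates
    ``i * (g_h - 1) / (H - 1)`` so that the four corners map exactly.  When
    the shapes already agree the grid is returned unchanged.
    """
    grid = np.asarray(grid, dtype=np.float64)
    gh, gw = grid.shape
    H, W = shape
    if (gh, gw) == (H, W):
        return grid.copy()
    rows = np.linspace(0.0, gh - 1.0, H) if H > 1 else np.zeros(1)
    cols = np.linspace(0.0, gw - 1.0, W) if W > 1 else np.zeros(1)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    r1 = np.minimum(r0 + 1, gh - 1)
    c1 = np.minimum(c0 + 1, gw - 1)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    top = grid[np.ix_(r0, c0)] * (1 - fc) + grid[np.ix_(r0, c1)] * fc
    bot = grid[np.ix_(r1, c0)] * (1 - fc) + grid[np.ix_(r1, c1)] * fc
    return top * (1 - fr) + bot * fr
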