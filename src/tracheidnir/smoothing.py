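"""Baseline smoothing comparators: moving average, Savitzky-Golay, loess, lowess.

All smoothers return a vector of the input length.

* ``moving_average`` — centered mean whose window shrinks at the edges.
* ``savitzky_golay`` — local least-squares polynomial (default order 2),
  with boundary points handled by fitting the edge polynomial and
  evaluating it (scipy's ``mode="interp"``).
* ``loess`` / ``lowess`` — locally weighted regression over the
  ``segment_size`` nearest points with tricube weights, local quadratic
  (loess) or local linear (lowess).  Distances are scaled by (half-window
  + 1) so every window point keeps a strictly positive weight, which keeps
  the quadratic fit well-posed even at the smallest window; no robustness
  iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import correlate1d
from scipy.signal import savgol_filter

__all__ = ["SmootherConfig", "smooth", "smooth_matrix", "SMOOTHER_METHODS"]

SMOOTHER_METHODS = ("moving_average", "savitzky_golay", "loess", "lowess")


@dataclass(frozen=True)
class SmootherConfig:
    method: str
    segment_size: int
    poly_order: int = 2

    def __post_init__(self):
        if self.method not in SMOOTHER_METHODS:
            raise ValueError(f"unknown smoother: {self.method!r}")
        if not (3 <= self.segment_size <= 25) or self.segment_size % 2 == 0:
            raise ValueError("segment_size must be odd and in [3, 25]")
        if self.method == "savitzky_golay" and self.poly_order >= self.segment_size:
            raise ValueError("poly_order must be < segment_size")


def _tricube(u: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3


def _local_fit_kernel(offsets: np.ndarray, eval_at: float, degree: int,
                      scale: float) -> np.ndarray:
    """Equivalent-kernel row of a tricube-weighted local polynomial fit.

    Returns e such that yhat(eval_at) = e @ y[window]."""
    w = _tricube((offsets - eval_at) / scale)
    A = np.vander(offsets - eval_at, degree + 1, increasing=True)
    AtW = A.T * w
    beta_op = np.linalg.solve(AtW @ A, AtW)
    return beta_op[0]  # intercept row evaluates the fit at eval_at


@lru_cache(maxsize=512)
def _loess_kernels(n: int, seg: int, degree: int):
    """Interior kernel + per-point edge kernels for a length-n regular grid."""
    h = seg // 2
    interior = _local_fit_kernel(np.arange(-h, h + 1, dtype=float), 0.0,
                                 degree, float(h + 1))
    edges = []
    for i in range(min(h, n)):
        offs = np.arange(seg, dtype=float)  # window = first seg points
        scale = float(max(offs.max() - i, i - offs.min()) + 1)
        edges.append(_local_fit_kernel(offs, float(i), degree, scale))
    return interior, edges


def _loess_like(X: np.ndarray, seg: int, degree: int) -> np.ndarray:
    n = X.shape[-1]
    if n <= seg:
        raise ValueError("signal must be longer than the segment size")
    h = seg // 2
    interior, edges = _loess_kernels(n, seg, degree)
    out = correlate1d(X, interior, axis=-1, mode="nearest")
    for i, e in enumerate(edges):
        out[..., i] = X[..., :seg] @ e
        out[..., n - 1 - i] = X[..., n - seg:] @ e[::-1]
    return out


def _moving_average(X: np.ndarray, seg: int) -> np.ndarray:
    n = X.shape[-1]
    if n <= seg:
        raise ValueError("signal must be longer than the segment size")
    h = seg // 2
    c = np.concatenate([np.zeros(X.shape[:-1] + (1,)), np.cumsum(X, axis=-1)], axis=-1)
    i = np.arange(n)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, n)
    return (c[..., hi] - c[..., lo]) / (hi - lo)


def smooth(spectrum: np.ndarray, config: SmootherConfig) -> np.ndarray:
    """Smooth one spectrum (or a batch along the last axis)."""
    X = np.asarray(spectrum, dtype=float)
    seg = config.segment_size
    if config.method == "moving_average":
        return _moving_average(X, seg)
    if config.method == "savitzky_golay":
        if X.shape[-1] <= seg:
            raise ValueError("signal must be longer than the segment size")
        return savgol_filter(X, seg, config.poly_order, axis=-1, mode="interp")
    if config.method == "loess":
        return _loess_like(X, seg, degree=2)
    return _loess_like(X, seg, degree=1)  # lowess


def smooth_matrix(X: np.ndarray, config: SmootherConfig) -> np.ndarray:
    """Row-wise smoothing of a samples x wavelengths matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return smooth(X, config)
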