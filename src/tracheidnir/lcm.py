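"""Local correlation maximization (LCM) hybrid-spectrum construction.

Given the same calibration spectra de-noised at decomposition levels
1..k, LCM computes, per wavelength, the Pearson correlation between the
de-noised absorbance and the trait (tracheid length), picks the level whose
correlation is strongest, and assembles a hybrid spectrum that takes each
wavelength's absorbance from its selected level.  The selection map is
fitted on calibration samples only and applied unchanged to held-out
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["CorrelationMap", "level_correlations", "select_levels",
           "construct_hybrid", "fit_lcm"]


@dataclass
class CorrelationMap:
    """Per-level, per-wavelength correlations and the selected levels.

    ``r_matrix`` has shape (k_max, n_wavelengths); row ``j`` holds the
    Pearson r between the level-(j+1) de-noised absorbance and the target.
    ``chosen_level`` is 1-based.
    """

    r_matrix: np.ndarray
    k_max: int
    chosen_level: np.ndarray | None = None


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each column of X against y; zero-variance columns -> 0."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    denom = sx * sy
    bad = denom == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance column(s); r set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    r[bad] = 0.0
    return r


def level_correlations(spectra_by_level, target: np.ndarray) -> CorrelationMap:
    """Correlation of each wavelength with the target at every level.

    Parameters
    ----------
    spectra_by_level : sequence of arrays, each (n_samples, n_wavelengths)
        De-noised calibration spectra at levels 1..k (same shape each).
    target : array, (n_samples,)
        Trait values of the same calibration samples.
    """
    y = np.asarray(target, dtype=float)
    mats = [np.asarray(m, dtype=float) for m in spectra_by_level]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("all level matrices must share one shape")
    if y.shape[0] != shape[0] or y.shape[0] < 3:
        raise ValueError("target length must equal sample count and be >= 3")
    r = np.vstack([_pearson_columns(m, y) for m in mats])
    return CorrelationMap(r_matrix=r, k_max=len(mats))


def select_levels(cmap: CorrelationMap, criterion: str = "abs") -> np.ndarray:
    """Pick, per wavelength, the level with the strongest correlation.

    ``criterion="abs"`` (default) maximizes |r|; ``"signed"`` maximizes r.
    Ties resolve to the smallest (least-processed) level.  Returns 1-based
    levels and stores them on ``cmap``.
    """
    score = np.abs(cmap.r_matrix) if criterion == "abs" else cmap.r_matrix
    chosen = np.argmax(score, axis=0) + 1  # argmax takes the first maximum
    cmap.chosen_level = chosen
    return chosen


def construct_hybrid(spectra_by_level, chosen_level: np.ndarray) -> np.ndarray:
    """Assemble the hybrid spectrum matrix from a per-wavelength level map.

    ``out[s, w] = spectra_by_level[chosen_level[w] - 1][s, w]`` — a pure
    selection; every output value exists verbatim in one input matrix.
    """
    mats = np.stack([np.asarray(m, dtype=float) for m in spectra_by_level])
    lev = np.asarray(chosen_level)
    if lev.min() < 1 or lev.max() > mats.shape[0]:
        raise ValueError("chosen level out of range")
    cols = np.arange(mats.shape[2])
    return mats[lev - 1, :, cols].T


def fit_lcm(spectra_by_level_cal, target_cal, criterion: str = "abs"):
    """Fit the LCM selection on calibration data.

    Returns ``(cmap, transform)`` where ``transform(spectra_by_level)``
    builds the hybrid matrix for any sample set de-noised at the same
    levels, without looking at its target.
    """
    cmap = level_correlations(spectra_by_level_cal, target_cal)
    chosen = select_levels(cmap, criterion=criterion)

    def transform(spectra_by_level):
        return construct_hybrid(spectra_by_level, chosen)

    return cmap, transform
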