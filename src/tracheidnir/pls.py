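"""NIPALS partial least squares (PLS1) and calibration statistics.

The regression pipeline mean-centers X and y (no autoscaling: absorbance
columns share units), extracts latent components by NIPALS with deflation,
and predicts through the accumulated regression vector.

Model quality is summarized by the chemometrics criteria
R^2, RMSE (divisor n), MAPE (%), SEC (sd of bias-corrected residuals,
divisor n-1) and RPD = SD/SEC, where SD is the reference standard
deviation of the set being scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "PredictionDiagnostics", "ModelReport",
           "fit_pls", "predict", "diagnostics", "evaluate"]


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # (p, A) NIPALS weight vectors
    x_loadings: np.ndarray   # (p, A)
    y_loadings: np.ndarray   # (A,)
    coef: np.ndarray         # (p,) regression vector on centered data
    tag: str = ""


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int,
            tag: str = "") -> PLSModel:
    """Fit a PLS1 model by NIPALS.

    Components whose weight norm collapses below 1e-12 stop the extraction
    early (with a warning); the model keeps the components found so far.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError("invalid number of components")
    if np.ptp(y) == 0:
        raise ValueError("target has zero variance")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    A = n_components
    for a in range(n_components):
        w = Xc.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            warnings.warn(f"component {a + 1}: weight norm ~0, truncating")
            A = a
            break
        w /= nw
        t = Xc @ w
        tt = float(t @ t)
        pa = Xc.T @ t / tt
        qa = float(yc @ t) / tt
        Xc = Xc - np.outer(t, pa)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
    W, P, q = W[:, :A], P[:, :A], q[:A]
    # regression vector: b = W (P' W)^{-1} q
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(n_components=A, x_mean=x_mean, y_mean=y_mean,
                    weights=W, x_loadings=P, y_loadings=q, coef=coef, tag=tag)


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict targets for new spectra on the training wavelength grid."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[-1] != model.x_mean.shape[0]:
        raise ValueError("wavelength grid mismatch")
    return (X_new - model.x_mean) @ model.coef + model.y_mean


@dataclass
class PredictionDiagnostics:
    """Calibration/validation statistics for one scored sample set."""

    n: int
    r2: float
    rmse: float
    mape: float
    sec: float
    rpd: float
    sd_of_reference: float


def diagnostics(y: np.ndarray, y_hat: np.ndarray,
                sd_of_reference: float | None = None) -> PredictionDiagnostics:
    """Compute R^2, RMSE, MAPE(%), SEC and RPD for one set.

    ``sd_of_reference`` defaults to the sample sd (n-1) of ``y`` — the
    reference sd of the set being scored; RPD = SD / SEC.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.any(y == 0):
        raise ValueError("MAPE undefined for zero reference values")
    resid = y - y_hat
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(sse / n))
    mape = float(np.mean(np.abs(resid / y)) * 100.0)
    centered = resid - resid.mean()
    sec = float(np.sqrt((centered @ centered) / (n - 1)))
    sd = float(np.std(y, ddof=1)) if sd_of_reference is None else float(sd_of_reference)
    if sec == 0:
        warnings.warn("SEC is zero; RPD reported as inf")
        rpd = float("inf")
    else:
        rpd = sd / sec
    return PredictionDiagnostics(n=n, r2=r2, rmse=rmse, mape=mape, sec=sec,
                                 rpd=rpd, sd_of_reference=sd)


@dataclass
class ModelReport:
    """Calibration + validation diagnostics for one pretreatment."""

    label: str
    n_components: int
    calibration: PredictionDiagnostics
    validation: PredictionDiagnostics | None = None

    def row(self) -> dict:
        d = {"model": self.label, "pcs": self.n_components,
             "Rc2": self.calibration.r2, "RMSEC": self.calibration.rmse,
             "MAPEc": self.calibration.mape, "SEC": self.calibration.sec,
             "RPDc": self.calibration.rpd}
        if self.validation is not None:
            d.update({"Rp2": self.validation.r2, "RMSEP": self.validation.rmse,
                      "SEP": self.validation.sec, "RPDp": self.validation.rpd})
        return d


def evaluate(model: PLSModel, X_cal, y_cal, X_val=None, y_val=None,
             label: str = "") -> ModelReport:
    """Score a fitted model on calibration (and optionally validation) data."""
    cal = diagnostics(y_cal, predict(model, X_cal))
    val = None
    if X_val is not None and y_val is not None:
        val = diagnostics(y_val, predict(model, X_val))
    return ModelReport(label=label or model.tag, n_components=model.n_components,
                       calibration=cal, validation=val)
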