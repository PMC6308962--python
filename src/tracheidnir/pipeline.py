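"""Study orchestration: wavelet screen, order/level sweeps, smoother sweep,
and the final pretreatment comparison with PLS calibration models.

Every sweep fits PLS on the (pretreated) calibration spectra only and ranks
rows lexicographically: highest Rc2, then lowest RMSEC, then lowest MAPEc.
Validation targets are read only when a fitted model is scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lcm as lcm_mod
from .lwt import DenoiseParams, denoise_matrix
from .pls import ModelReport, diagnostics, evaluate, fit_pls, predict
from .smoothing import SmootherConfig, smooth_matrix
from .synthetic import SpectraSet

log = logging.getLogger(__name__)

__all__ = ["SweepResult", "FinalComparison", "screen_wavelets", "sweep_order",
           "sweep_level", "sweep_smoothers", "final_comparison",
           "DEFAULT_PCS", "SCREEN_WAVELETS", "SEGMENT_SIZES"]

DEFAULT_PCS = 7
SCREEN_WAVELETS = ("sym5", "bior5.5", "rbio5.5", "db5")
SEGMENT_SIZES = tuple(range(3, 26, 2))


@dataclass
class SweepResult:
    """A table of candidate pretreatments with calibration statistics."""

    table: pd.DataFrame

    @property
    def best_row(self) -> pd.Series:
        ranked = self.table.sort_values(
            by=["Rc2", "RMSEC", "MAPEc"], ascending=[False, True, True],
            kind="mergesort")
        return ranked.iloc[0]


def _cal_stats(X_cal: np.ndarray, y_cal: np.ndarray, pcs: int) -> dict:
    model = fit_pls(X_cal, y_cal, pcs)
    d = diagnostics(y_cal, predict(model, X_cal))
    return {"pcs": model.n_components, "Rc2": d.r2, "RMSEC": d.rmse,
            "MAPEc": d.mape, "SEC": d.sec, "RPDc": d.rpd}


def screen_wavelets(data: SpectraSet, level: int = 5,
                    pcs: int = DEFAULT_PCS,
                    wavelets=SCREEN_WAVELETS) -> SweepResult:
    """De-noise with each candidate mother wavelet at a fixed level and
    rank the resulting calibration models."""
    cal = data.calibration
    rows = []
    for name in wavelets:
        params = DenoiseParams.make(name, level)
        Xd = denoise_matrix(cal.absorbance, params)
        rows.append({"label": name, "wavelet": name, "level": level,
                     "threshold": "universal_global_hard",
                     **_cal_stats(Xd, cal.target, pcs)})
    res = SweepResult(pd.DataFrame(rows))
    log.info("wavelet screen: best %s", res.best_row["label"])
    return res


def sweep_order(data: SpectraSet, orders=range(1, 9), level: int = 5,
                pcs: int = DEFAULT_PCS) -> SweepResult:
    """Sweep the Daubechies order at a fixed decomposition level."""
    return screen_wavelets(data, level=level, pcs=pcs,
                           wavelets=tuple(f"db{n}" for n in orders))


def sweep_level(data: SpectraSet, wavelet: str = "db2", levels=range(1, 6),
                pcs: int = DEFAULT_PCS) -> SweepResult:
    """Sweep the decomposition level for one mother wavelet."""
    cal = data.calibration
    rows = []
    for k in levels:
        params = DenoiseParams.make(wavelet, k)
        Xd = denoise_matrix(cal.absorbance, params)
        rows.append({"label": f"{wavelet}, k={k}", "wavelet": wavelet,
                     "level": k, "threshold": "universal_global_hard",
                     **_cal_stats(Xd, cal.target, pcs)})
    res = SweepResult(pd.DataFrame(rows))
    log.info("level sweep (%s): best %s", wavelet, res.best_row["label"])
    return res


def sweep_smoothers(data: SpectraSet, methods=None, segments=SEGMENT_SIZES,
                    pcs: int = DEFAULT_PCS) -> SweepResult:
    """Grid of comparator smoothers x segment sizes."""
    from .smoothing import SMOOTHER_METHODS
    methods = methods or SMOOTHER_METHODS
    cal = data.calibration
    rows = []
    for method in methods:
        for seg in segments:
            cfg = SmootherConfig(method=method, segment_size=seg)
            Xs = smooth_matrix(cal.absorbance, cfg)
            rows.append({"label": f"{method}, s={seg}", "method": method,
                         "segment_size": seg,
                         **_cal_stats(Xs, cal.target, pcs)})
    res = SweepResult(pd.DataFrame(rows))
    log.info("smoother sweep: best %s", res.best_row["label"])
    return res


@dataclass
class FinalComparison:
    """Final pretreatment comparison (one report row per model), the
    model x prediction-set cross matrix of Rp2, and the wavelength-wise
    correlation curves of each pretreated calibration matrix vs target."""

    reports: list
    cross_rp2: pd.DataFrame
    correlation_curves: pd.DataFrame

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.reports])


def _pretreatments(data: SpectraSet, wavelet: str, level: int):
    """Build the four pretreated (cal, val) matrix pairs.

    LWT-LCM: de-noise at levels 1..level, fit the per-wavelength level
    selection on the calibration set, apply the same map to both sets.
    """
    cal, val = data.calibration, data.prediction
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    out["Raw"] = (cal.absorbance.copy(), val.absorbance.copy())

    params = DenoiseParams.make(wavelet, level)
    out["LWT"] = (denoise_matrix(cal.absorbance, params, path="auto"),
                  denoise_matrix(val.absorbance, params, path="auto"))
    out["WT"] = (denoise_matrix(cal.absorbance, params, path="filterbank"),
                 denoise_matrix(val.absorbance, params, path="filterbank"))

    by_level_cal = [denoise_matrix(cal.absorbance, DenoiseParams.make(wavelet, k))
                    for k in range(1, level + 1)]
    by_level_val = [denoise_matrix(val.absorbance, DenoiseParams.make(wavelet, k))
                    for k in range(1, level + 1)]
    cmap, transform = lcm_mod.fit_lcm(by_level_cal, cal.target)
    out["LWT-LCM"] = (transform(by_level_cal), transform(by_level_val))
    return out


def final_comparison(data: SpectraSet, wavelet: str = "db2", level: int = 4,
                     pcs: int = DEFAULT_PCS) -> FinalComparison:
    """Fit the Raw / LWT / LWT-LCM / WT models and compare them."""
    cal, val = data.calibration, data.prediction
    pre = _pretreatments(data, wavelet, level)
    order = ["Raw", "LWT", "LWT-LCM", "WT"]

    models, reports = {}, []
    for name in order:
        Xc, Xv = pre[name]
        model = fit_pls(Xc, cal.target, pcs, tag=name)
        models[name] = model
        reports.append(evaluate(model, Xc, cal.target, Xv, val.target,
                                label=name))
        log.info("final model %s: Rc2=%.3f", name, reports[-1].calibration.r2)

    cross = pd.DataFrame(
        {pset: [diagnostics(val.target, predict(models[m], pre[pset][1])).r2
                for m in order] for pset in order},
        index=order)
    cross.index.name = "model"
    cross.columns.name = "prediction_set"

    curves = pd.DataFrame({"wavelength": data.wavelengths})
    for name in order:
        Xc, _ = pre[name]
        curves[name] = lcm_mod._pearson_columns(Xc, cal.target)

    return FinalComparison(reports=reports, cross_rp2=cross,
                           correlation_curves=curves)
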