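"""NIPALS PLS1 and the calibration statistics (R2, RMSE, MAPE, SEC, RPD)."""

import numpy as np
import pytest

from tracheidnir.pls import diagnostics, evaluate, fit_pls, predict
from tracheidnir.synthetic import CohortConfig, simulate_cohort


def _single_band_data(rng, n=30, p=50):
    band = np.exp(-0.5 * ((np.arange(p) - 25) / 5.0) ** 2)
    y = rng.uniform(1, 4, size=n)
    X = 0.5 + np.outer(y, band)
    return X, y


def test_single_band_exact_fit_with_one_component(rng):
    X, y = _single_band_data(rng)
    model = fit_pls(X, y, 1)
    assert np.abs(predict(model, X) - y).max() < 1e-8


def test_full_rank_pls_equals_ols(rng):
    """With as many components as the rank of X, PLS predictions coincide
    with the ordinary least-squares fit (normal-equations oracle)."""
    n, p = 40, 6
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    model = fit_pls(X, y, p)
    Xc = X - X.mean(axis=0)
    beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
    y_ols = Xc @ beta + y.mean()
    assert np.abs(predict(model, X) - y_ols).max() < 1e-6


def test_matches_reference_pls_implementation(rng):
    from sklearn.cross_decomposition import PLSRegression
    X = rng.normal(size=(25, 40))
    y = rng.normal(size=25)
    model = fit_pls(X, y, 3)
    ref = PLSRegression(n_components=3, scale=False).fit(X, y.reshape(-1, 1))
    assert np.allclose(predict(model, X), ref.predict(X).ravel(), atol=1e-8)


def test_prediction_of_training_mean_is_mean_target(rng):
    X, y = _single_band_data(rng)
    model = fit_pls(X, y, 3)
    assert predict(model, X.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-8)


def test_prediction_is_affine(rng):
    X, y = _single_band_data(rng)
    model = fit_pls(X, y, 2)
    x1, x2 = X[0], X[1]
    for alpha in (0.25, 0.5, 0.9):
        blend = alpha * x1 + (1 - alpha) * x2
        expected = alpha * predict(model, x1) + (1 - alpha) * predict(model, x2)
        assert predict(model, blend) == pytest.approx(float(expected), abs=1e-8)


def test_grid_mismatch_and_degenerate_target_rejected(rng):
    X, y = _single_band_data(rng)
    model = fit_pls(X, y, 1)
    with pytest.raises(ValueError):
        predict(model, X[:, :-1])
    with pytest.raises(ValueError):
        fit_pls(X, np.full_like(y, 2.0), 1)


def test_component_truncation_on_collapsed_weights(rng):
    X, y = _single_band_data(rng)  # rank-1 signal: component 2 is empty
    with pytest.warns(UserWarning):
        model = fit_pls(X, y, 3)
    assert model.n_components < 3


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def test_perfect_prediction_statistics():
    y = np.array([1.0, 2.0, 3.0])
    with pytest.warns(UserWarning):  # SEC = 0 -> RPD inf
        d = diagnostics(y, y)
    assert d.r2 == 1.0 and d.rmse == 0.0 and d.mape == 0.0
    assert np.isinf(d.rpd)


def test_hand_computed_toy_statistics():
    d = diagnostics(np.array([1.0, 2.0, 3.0]), np.array([1.1, 1.9, 3.2]))
    assert d.r2 == pytest.approx(0.97, abs=5e-5)
    assert d.rmse == pytest.approx(np.sqrt(0.06 / 3), abs=5e-5)
    assert d.mape == pytest.approx(7.2222, abs=5e-4)


def test_hand_computed_sec_and_rpd():
    y = np.array([1.0, 2.0])
    y_hat = y - np.array([0.1, -0.1])  # residuals [0.1, -0.1]
    d = diagnostics(y, y_hat, sd_of_reference=0.667)
    assert d.sec == pytest.approx(np.sqrt(0.02), abs=5e-5)
    assert d.rpd == pytest.approx(0.667 / np.sqrt(0.02), abs=5e-4)


def test_constant_prediction_has_zero_r2(rng):
    y = rng.normal(size=20)
    d = diagnostics(y, np.full(20, y.mean()))
    assert d.r2 == pytest.approx(0.0, abs=1e-12)


def test_shift_invariance_of_r2_and_rmse(rng):
    y = rng.uniform(1, 4, size=15)
    y_hat = y + rng.normal(scale=0.1, size=15)
    d0 = diagnostics(y, y_hat)
    d1 = diagnostics(y + 5, y_hat + 5)
    assert d1.r2 == pytest.approx(d0.r2)
    assert d1.rmse == pytest.approx(d0.rmse)
    assert d1.mape != pytest.approx(d0.mape)  # MAPE is scale-anchored


def test_sec_bounded_by_rmse(rng):
    for s in range(10):
        r = np.random.default_rng(s)
        y = r.uniform(1, 4, size=12)
        y_hat = y + r.normal(scale=0.3, size=12) + 0.2
        d = diagnostics(y, y_hat)
        assert d.sec <= d.rmse * np.sqrt(12 / 11) + 1e-12


def test_mape_rejects_zero_reference():
    with pytest.raises(ValueError):
        diagnostics(np.array([0.0, 1.0]), np.array([0.1, 1.0]))


# ---------------------------------------------------------------------------
# behaviour on synthetic cohorts
# ---------------------------------------------------------------------------

def test_noiseless_cohort_recovered_exactly():
    cfg = CohortConfig(trait_link_sd_mm=0.0, noise_sd=0.0,
                       drift_amplitude=0.0, scatter_sd=0.0, seed=3)
    data = simulate_cohort(cfg)
    cal = data.calibration
    model = fit_pls(cal.absorbance, cal.target, 3)
    d = diagnostics(cal.target, predict(model, cal.absorbance))
    assert d.r2 >= 0.999


def test_default_cohort_calibration_regime():
    """Raw-spectra PLS on default cohorts lands in the working regime of
    wood NIR calibrations (Rc2 above 0.7), across seeds."""
    for s in range(20):
        data = simulate_cohort(seed=700 + s)
        cal = data.calibration
        model = fit_pls(cal.absorbance, cal.target, 7)
        d = diagnostics(cal.target, predict(model, cal.absorbance))
        assert d.r2 > 0.7


def test_evaluate_produces_full_report(default_cohort):
    cal = default_cohort.calibration
    val = default_cohort.prediction
    model = fit_pls(cal.absorbance, cal.target, 7, tag="Raw")
    rep = evaluate(model, cal.absorbance, cal.target,
                   val.absorbance, val.target)
    row = rep.row()
    for key in ("Rc2", "RMSEC", "SEC", "RPDc", "Rp2", "RMSEP", "SEP", "RPDp"):
        assert key in row
    assert row["RPDc"] == pytest.approx(
        rep.calibration.sd_of_reference / rep.calibration.sec)
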