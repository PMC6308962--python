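"""Lifting wavelet transform: equivalence with a reference DWT, perfect
reconstruction, thresholding rules, and de-noising behaviour."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from tracheidnir.lwt import (DenoiseParams, apply_threshold, denoise,
                             denoise_matrix, estimate_sigma, forward_lwt,
                             inverse_lwt, universal_threshold)
from tracheidnir.wavelets import (SUPPORTED_WAVELETS, WaveletSpec,
                                  daubechies_scaling)

ORTHOGONAL = [w for w in SUPPORTED_WAVELETS if not w.startswith(("bior", "rbio"))]
BIORTHOGONAL = ["bior5.5", "rbio5.5"]


# ---------------------------------------------------------------------------
# filter construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("order", range(1, 9))
def test_daubechies_filters_match_reference(order):
    ref = np.array(pywt.Wavelet(f"db{order}").rec_lo)
    assert np.allclose(daubechies_scaling(order), ref, atol=1e-12)


@pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
def test_filter_banks_match_reference(name):
    ours = WaveletSpec.from_name(name).filter_bank()
    ref = pywt.Wavelet(name)
    for mine, theirs in zip(ours, ref.filter_bank):
        assert np.allclose(mine, np.array(theirs), atol=1e-12)


def test_unknown_wavelet_rejected():
    with pytest.raises(ValueError):
        WaveletSpec.from_name("coif3").filter_bank()
    with pytest.raises(ValueError):
        forward_lwt(np.ones(16), "db9", 1)


# ---------------------------------------------------------------------------
# forward transform vs convolution reference
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
def test_forward_matches_reference_dwt(name, rng):
    """Our transform (lifting path for db1/db2, filter bank otherwise)
    reproduces the periodized convolution DWT on 100 random signals."""
    X = rng.normal(size=(100, 64))
    res = forward_lwt(X, name, 1)
    ca_ref, cd_ref = pywt.dwt(X, name, mode="periodization", axis=-1)
    assert np.allclose(res.approximation, ca_ref, atol=1e-10)
    assert np.allclose(res.details[0], cd_ref, atol=1e-10)


def test_multilevel_matches_reference_wavedec(rng):
    x = rng.normal(size=64)
    res = forward_lwt(x, "db3", 3)
    coeffs = pywt.wavedec(x, "db3", mode="periodization", level=3)
    assert np.allclose(res.approximation, coeffs[0], atol=1e-8)
    # details stored finest-first; pywt returns coarsest-first after cA
    for mine, theirs in zip(res.details, coeffs[:0:-1]):
        assert np.allclose(mine, theirs, atol=1e-8)


@pytest.mark.parametrize("name", ["db1", "db2"])
def test_lifting_path_equals_filterbank_path(name, rng):
    X = rng.normal(size=(100, 256))
    lift = forward_lwt(X, name, 3, path="lifting")
    conv = forward_lwt(X, name, 3, path="filterbank")
    assert np.allclose(lift.approximation, conv.approximation, atol=1e-10)
    for a, b in zip(lift.details, conv.details):
        assert np.allclose(a, b, atol=1e-10)
    back = inverse_lwt(lift, path="lifting")
    assert np.allclose(back, X, atol=1e-10)


def test_lifting_path_unavailable_for_higher_orders():
    with pytest.raises(ValueError):
        forward_lwt(np.ones(64), "db5", 1, path="lifting")


# ---------------------------------------------------------------------------
# perfect reconstruction and transform structure
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name", SUPPORTED_WAVELETS)
@pytest.mark.parametrize("n", [64, 256, 2048])
def test_perfect_reconstruction(name, n, rng):
    tol = 1e-8 if name in ORTHOGONAL else 1e-6
    x = rng.normal(size=n)
    for level in range(1, 6):
        res = forward_lwt(x, name, level)
        assert np.abs(inverse_lwt(res) - x).max() < tol


def test_zero_signal_maps_to_zero_coefficients():
    res = forward_lwt(np.zeros(128), "sym5", 3)
    assert not res.approximation.any()
    assert not any(d.any() for d in res.details)


def test_constant_signal_haar_level1():
    res = forward_lwt(np.full(64, 3.5), "db1", 1)
    assert np.allclose(res.details[0], 0.0, atol=1e-12)
    assert np.allclose(res.approximation, 3.5 * np.sqrt(2), atol=1e-12)


def test_constant_survives_detail_zeroing():
    res = forward_lwt(np.full(64, 2.75), "db2", 3)
    res.details = [np.zeros_like(d) for d in res.details]
    assert np.allclose(inverse_lwt(res), 2.75, atol=1e-10)


@given(a=st.floats(-5, 5), b=st.floats(-5, 5))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_forward_is_linear(a, b):
    r = np.random.default_rng(7)
    x, y = r.normal(size=64), r.normal(size=64)
    lhs = forward_lwt(a * x + b * y, "db4", 2)
    fx, fy = forward_lwt(x, "db4", 2), forward_lwt(y, "db4", 2)
    assert np.allclose(lhs.approximation,
                       a * fx.approximation + b * fy.approximation, atol=1e-8)
    for la, da, db_ in zip(lhs.details, fx.details, fy.details):
        assert np.allclose(la, a * da + b * db_, atol=1e-8)


@pytest.mark.parametrize("name", ORTHOGONAL)
def test_energy_preserved_orthogonal(name, rng):
    x = rng.normal(size=256)
    res = forward_lwt(x, name, 4)
    energy = (res.approximation ** 2).sum() + sum((d ** 2).sum()
                                                  for d in res.details)
    assert np.isclose(energy, (x ** 2).sum(), rtol=1e-6)


def test_odd_length_roundtrip(rng):
    x = rng.normal(size=100)  # second stage sees an odd length (50 -> 25)
    res = forward_lwt(x, "db2", 3)
    assert np.allclose(inverse_lwt(res), x, atol=1e-8)


def test_level_too_deep_rejected():
    with pytest.raises(ValueError):
        forward_lwt(np.ones(16), "db1", 5)


def test_inconsistent_coefficient_shapes_rejected(rng):
    res = forward_lwt(rng.normal(size=64), "db2", 2)
    res.details[0] = res.details[0][:-3]
    with pytest.raises(ValueError):
        inverse_lwt(res)


# ---------------------------------------------------------------------------
# sigma estimate and thresholds
# ---------------------------------------------------------------------------

def test_sigma_definition():
    assert estimate_sigma(np.array([0.6745, -0.6745, 0.6745])) == pytest.approx(1.0)
    assert estimate_sigma(np.zeros(4)) == 0.0
    with pytest.raises(ValueError):
        estimate_sigma(np.array([]))


def test_sigma_consistency_on_gaussian_noise():
    r = np.random.default_rng(1234)
    draws = r.normal(scale=2.0, size=10_000)
    assert 1.9 < estimate_sigma(draws) < 2.1


def test_universal_threshold_closed_form():
    assert universal_threshold(0.0, 100) == 0.0
    assert universal_threshold(1.0, 2048) == pytest.approx(3.9050, abs=5e-5)
    assert universal_threshold(3.0, 500) == pytest.approx(
        3 * universal_threshold(1.0, 500))
    with pytest.raises(ValueError):
        universal_threshold(1.0, 1)
    with pytest.raises(ValueError):
        universal_threshold(-0.1, 10)


def test_threshold_rules():
    w = np.array([3.0, -1.0, 0.5])
    assert np.array_equal(apply_threshold(w, 0.0, "hard"), w)
    assert np.array_equal(apply_threshold(w, 1.0, "hard"), [3.0, 0.0, 0.0])
    assert np.allclose(apply_threshold(w, 1.0, "soft"), [2.0, 0.0, 0.0])
    # tie rule: |w| == lambda maps to zero
    assert apply_threshold(np.array([1.0]), 1.0, "hard")[0] == 0.0
    with pytest.raises(ValueError):
        apply_threshold(w, -1.0, "hard")


# ---------------------------------------------------------------------------
# de-noising
# ---------------------------------------------------------------------------

def test_denoise_is_identity_on_constants():
    x = np.full(2048, 0.7)
    out = denoise(x, DenoiseParams.make("db2", 4))
    assert np.abs(out - x).max() < 1e-8


def test_infinite_threshold_keeps_approximation_only(rng):
    x = rng.normal(size=256)
    params = DenoiseParams.make("db2", 3)
    out = denoise(x, params, threshold_override=np.inf)
    res = forward_lwt(x, "db2", 3)
    res.details = [np.zeros_like(d) for d in res.details]
    assert np.allclose(out, inverse_lwt(res), atol=1e-10)


def test_denoising_reduces_rmse_on_noisy_spectra():
    from tracheidnir.synthetic import CohortConfig, synthesize_spectrum
    clean = synthesize_spectrum(3.3, 20, CohortConfig())
    params = DenoiseParams.make("db2", 4)
    wins = 0
    for s in range(20):
        r = np.random.default_rng(5000 + s)
        noisy = clean + 0.005 * r.normal(size=clean.size)
        den = denoise(noisy, params)
        wins += np.mean((den - clean) ** 2) < np.mean((noisy - clean) ** 2)
    assert wins >= 19


def test_denoise_matrix_matches_rowwise_denoise(rng):
    X = rng.normal(size=(5, 256)) + 1.0
    params = DenoiseParams.make("db2", 3)
    rows = np.vstack([denoise(X[i], params) for i in range(5)])
    assert np.allclose(denoise_matrix(X, params), rows, atol=1e-10)
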