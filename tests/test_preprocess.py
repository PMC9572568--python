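"""Pre-treatments: mean centering, SNV, Savitzky-Golay derivatives, pipelines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikedspec import PreprocessingPipeline, mean_center_fit_apply, sg_derivative, snv
from spikedspec.errors import (
    DegenerateInputError,
    NotFittedError,
    ParameterError,
    ZeroVarianceError,
)
from spikedspec.preprocess import apply_mean_center


# -- mean centering ---------------------------------------------------------

def test_identical_rows_center_to_zero():
    X = np.tile([1.0, 2.0, 3.0], (4, 1))
    Xc, means = mean_center_fit_apply(X)
    np.testing.assert_array_equal(Xc, np.zeros_like(X))
    np.testing.assert_array_equal(means, [1.0, 2.0, 3.0])


def test_centered_columns_sum_to_zero(rng):
    X = rng.normal(size=(5, 4))
    Xc, _ = mean_center_fit_apply(X)
    assert np.all(np.abs(Xc.sum(axis=0)) < 1e-10)


def test_applying_stored_means_reproduces_fit(rng):
    X = rng.normal(size=(6, 3))
    Xc, means = mean_center_fit_apply(X)
    np.testing.assert_array_equal(apply_mean_center(X, means), Xc)


def test_single_row_is_degenerate():
    with pytest.raises(DegenerateInputError):
        mean_center_fit_apply(np.ones((1, 5)))


# -- SNV --------------------------------------------------------------------

def test_snv_rows_have_mean_zero_sd_one(rng):
    X = rng.normal(loc=3.0, scale=2.0, size=(4, 100))
    Z = snv(X)
    assert np.all(np.abs(Z.mean(axis=1)) < 1e-12)
    assert np.all(np.abs(Z.std(axis=1, ddof=1) - 1.0) < 1e-12)


def test_snv_fixed_point():
    x = np.array([-1.0, 0.0, 1.0])
    x = (x - x.mean()) / x.std(ddof=1)
    np.testing.assert_allclose(snv(x[None, :])[0], x, atol=1e-14)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(a=st.floats(0.1, 50.0), b=st.floats(-10.0, 10.0),
       seed=st.integers(0, 100))
def test_snv_affine_invariance(a, b, seed):
    x = np.random.default_rng(seed).normal(size=(1, 30))
    np.testing.assert_allclose(snv(a * x + b), snv(x), atol=1e-8)


def test_snv_constant_row_names_sample():
    X = np.vstack([np.arange(5.0), np.full(5, 2.0)])
    with pytest.raises(ZeroVarianceError, match="s2"):
        snv(X, sample_ids=np.array(["s1", "s2"]))


def test_snv_commutes_with_row_permutation(rng):
    X = rng.normal(size=(5, 20))
    perm = rng.permutation(5)
    np.testing.assert_allclose(snv(X)[perm], snv(X[perm]), atol=1e-14)


# -- Savitzky-Golay derivatives --------------------------------------------

def _grid(n=101):
    return np.arange(8000.0, 8000.0 - 4 * n, -4.0)


def test_constant_spectrum_derivative_is_zero():
    wn = _grid()
    d, wn_out = sg_derivative(np.full((1, len(wn)), 3.7), wn, order=1)
    np.testing.assert_allclose(d, 0.0, atol=1e-12)
    assert len(wn_out) == len(wn) - 14  # half-window trimmed each side


def test_first_derivative_of_cubic_matches_analytic():
    wn = _grid()
    coeffs = (2e-9, -3e-5, 0.11, -40.0)  # a nu^3 + b nu^2 + c nu + d
    x = np.polyval(coeffs, wn)[None, :]
    d, wn_out = sg_derivative(x, wn, order=1, window=15, polyorder=3)
    expected = np.polyval(np.polyder(coeffs), wn_out)
    np.testing.assert_allclose(d[0], expected, rtol=1e-8)


def test_second_derivative_of_quadratic_is_two_a():
    wn = _grid()
    a = 4e-6
    x = (a * wn ** 2)[None, :]
    d, _ = sg_derivative(x, wn, order=2)
    np.testing.assert_allclose(d[0], 2 * a, rtol=1e-8)


def test_derivative_sign_respects_increasing_wavenumber():
    # spectrum = 0.01 * nu is increasing in wavenumber, so D1 must be +0.01
    # even though the axis is stored descending
    wn = _grid()
    d, _ = sg_derivative((0.01 * wn)[None, :], wn, order=1)
    np.testing.assert_allclose(d[0], 0.01, rtol=1e-10)


@pytest.mark.parametrize("kwargs", [
    {"order": 1, "window": 14, "polyorder": 2},  # even window
    {"order": 1, "window": 5, "polyorder": 5},   # window <= polyorder
    {"order": 2, "window": 7, "polyorder": 1},   # polyorder < order
    {"order": 3},                                 # unsupported order
])
def test_sg_parameter_validation(kwargs):
    wn = _grid(31)
    with pytest.raises(ParameterError):
        sg_derivative(np.zeros((1, len(wn))), wn, **kwargs)


# -- pipelines --------------------------------------------------------------

def test_pipeline_labels_and_order():
    assert [s.kind for s in PreprocessingPipeline("SNV+MC").steps] == ["snv", "mc"]
    with pytest.raises(ParameterError):
        PreprocessingPipeline("MC+SNV")  # MC must come last
    with pytest.raises(ParameterError):
        PreprocessingPipeline("XX+MC")


def test_transform_before_fit_rejected(rng):
    pipe = PreprocessingPipeline("MC")
    with pytest.raises(NotFittedError):
        pipe.transform(rng.normal(size=(2, 5)), np.arange(5)[::-1].astype(float))


def test_fitted_pipeline_is_deterministic_on_new_data(rng):
    wn = _grid(51)
    train = rng.normal(size=(8, 51)) + 1.0
    new = rng.normal(size=(3, 51)) + 1.0
    pipe = PreprocessingPipeline("D1+MC").fit(train, wn)
    np.testing.assert_array_equal(pipe.transform(new, wn), pipe.transform(new, wn))


def test_derivative_pipeline_propagates_shrunken_axis(rng):
    wn = _grid(51)
    pipe = PreprocessingPipeline("D2+MC").fit(rng.normal(size=(4, 51)), wn)
    assert len(pipe.wavenumbers_out) == 51 - 14


def test_mc_pipeline_centers_training_data(rng):
    wn = _grid(21)
    X = rng.normal(size=(6, 21))
    out = PreprocessingPipeline("MC").fit_transform(X, wn)
    assert np.all(np.abs(out.sum(axis=0)) < 1e-10)
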