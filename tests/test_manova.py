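"""Core estimator: noise precision, betas, distinctness, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvdecode import (
    CrossValidatedMANOVA,
    Request,
    estimate_noise_precision,
    expected_cross,
    fit_betas,
    pattern_distinctness,
    simulate_subject,
    smooth_timecourse,
)
from cvdecode.manova import hann_kernel, smooth_grid
from conftest import cheap_params


# ---------------------------------------------------------------------------
# noise precision
# ---------------------------------------------------------------------------

def _two_condition_X(n_per):
    X = np.zeros((2 * n_per, 2))
    X[:n_per, 0] = 1.0
    X[n_per:, 1] = 1.0
    return X


def test_full_shrinkage_gives_scaled_identity():
    rng = np.random.default_rng(0)
    Y = rng.standard_normal((30, 4))
    noise = estimate_noise_precision(Y, _two_condition_X(15), lam=1.0)
    P = noise.precision
    off = P - np.diag(np.diag(P))
    assert np.allclose(off, 0.0, atol=1e-12)
    assert np.allclose(np.diag(P), P[0, 0])


def test_two_channel_toy_matches_explicit_formula():
    """Hand-written residuals: precision equals the explicit shrinkage
    inverse times (fE − p − 1), computed by brute-force matrix algebra."""
    rng = np.random.default_rng(1)
    Y = rng.standard_normal((12, 2))
    X = _two_condition_X(6)
    lam = 0.05
    noise = estimate_noise_precision(Y, X, lam=lam)
    # independent evaluation
    B = np.linalg.pinv(X) @ Y
    Xi = Y - X @ B
    S = Xi.T @ Xi
    S_reg = (1 - lam) * S + lam * (np.trace(S) / 2) * np.eye(2)
    fE = 12 - 2
    expect = (fE - 2 - 1) * np.linalg.inv(S_reg)
    assert np.allclose(noise.precision, expect, atol=1e-12)
    assert noise.fE == fE


def test_white_noise_precision_is_near_identity():
    """Unit-variance residuals at large fE: E[(fE−p−1)·S_reg⁻¹] ≈ I."""
    rng = np.random.default_rng(2)
    P_acc = np.zeros((3, 3))
    n_rep = 200
    for _ in range(n_rep):
        Y = rng.standard_normal((100, 3))
        P_acc += estimate_noise_precision(Y, _two_condition_X(50), lam=0.0).precision
    assert np.allclose(P_acc / n_rep, np.eye(3), atol=0.05)


def test_insufficient_trials_for_noise_estimate():
    rng = np.random.default_rng(3)
    with pytest.raises(ValueError, match="fE"):
        estimate_noise_precision(rng.standard_normal((6, 5)),
                                 _two_condition_X(3))


# ---------------------------------------------------------------------------
# betas
# ---------------------------------------------------------------------------

def test_betas_reduce_to_condition_means():
    rng = np.random.default_rng(4)
    Y = rng.standard_normal((2, 3))
    X = np.eye(2)
    assert np.allclose(fit_betas(Y, X), Y)  # one trial per condition
    Y2 = np.vstack([Y, Y])  # duplicated trials -> mean = original rows
    X2 = np.vstack([X, X])
    assert np.allclose(fit_betas(Y2, X2), Y)


def test_betas_match_normal_equations():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((20, 4))
    Y = rng.standard_normal((20, 3))
    expect = np.linalg.solve(X.T @ X, X.T @ Y)
    assert np.allclose(fit_betas(Y, X), expect, atol=1e-10)


def test_rank_deficient_design_names_empty_conditions():
    X = np.zeros((4, 3))
    X[:, 0] = 1.0
    with pytest.raises(ValueError, match=r"\[1, 2\]"):
        fit_betas(np.zeros((4, 2)), X)


# ---------------------------------------------------------------------------
# pattern distinctness
# ---------------------------------------------------------------------------

def test_zero_training_betas_give_zero_D():
    X = np.vstack([np.eye(2)] * 3)
    D = pattern_distinctness(
        np.zeros((2, 2)), np.ones((2, 2)), X,
        np.array([1.0, -1.0]), np.array([1.0, -1.0]), np.eye(2), 6,
    )
    assert D == 0.0


def test_zero_contrast_rejected():
    X = np.vstack([np.eye(2)] * 2)
    with pytest.raises(ValueError, match="zero"):
        pattern_distinctness(np.ones((2, 2)), np.ones((2, 2)), X,
                             np.zeros(2), np.array([1.0, -1.0]), np.eye(2), 4)


def test_balanced_two_condition_reduction():
    """Balanced 2-condition, identity precision: D equals the explicit
    projector/trace evaluation, which reduces to (m/2n)·δ̂_train'δ̂_test."""
    rng = np.random.default_rng(6)
    m, p = 4, 2
    B_tr = rng.standard_normal((2, p))
    B_te = rng.standard_normal((2, p))
    X_te = np.vstack([np.eye(2)] * m)
    c = np.array([1.0, -1.0])
    n = 2 * m
    D = pattern_distinctness(B_tr, B_te, X_te, c, c, np.eye(p), n)
    # brute-force trace formula with explicit projector matrices
    C = c[:, None]
    P = C @ np.linalg.inv(C.T @ C) @ C.T
    D_brute = np.trace(B_tr.T @ P @ (X_te.T @ X_te) @ P @ B_te @ np.eye(p)) / n
    assert np.isclose(D, D_brute, atol=1e-12)
    delta_tr, delta_te = B_tr[0] - B_tr[1], B_te[0] - B_te[1]
    assert np.isclose(D, m / (2 * n) * delta_tr @ delta_te, atol=1e-12)


def test_contrast_scaling_invariance():
    rng = np.random.default_rng(7)
    B_tr, B_te = rng.standard_normal((2, 2, 3))
    X_te = np.vstack([np.eye(2)] * 5)
    c = np.array([0.5, -0.5])
    D1 = pattern_distinctness(B_tr, B_te, X_te, c, c, np.eye(3), 10)
    D2 = pattern_distinctness(B_tr, B_te, X_te, 4 * c, 4 * c, np.eye(3), 10)
    assert np.isclose(D1, D2, atol=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    D1=st.floats(-0.5, 0.5, allow_nan=False),
    D2=st.floats(-0.5, 0.5, allow_nan=False),
)
def test_expected_cross_properties(D1, D2):
    E = expected_cross(D1, D2)
    assert np.isclose(abs(E), np.sqrt(abs(D1 * D2)), atol=1e-12)
    assert E * np.sign(D1) * np.sign(D2) >= 0


@pytest.mark.parametrize(
    "D1, D2, expect",
    [(0.04, 0.01, 0.02), (0.07, 0.07, 0.07), (0.09, -0.01, -0.03)],
)
def test_expected_cross_values(D1, D2, expect):
    assert np.isclose(expected_cross(D1, D2), expect, atol=1e-12)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_smoothing_preserves_constants_and_unit_sum():
    x = np.full(60, 3.7)
    out = smooth_timecourse(x, fs=20.0, fwhm=0.5)
    assert np.allclose(out, 3.7, atol=1e-12)
    assert np.isclose(hann_kernel(0.5, 20.0).sum(), 1.0)


def test_impulse_response_has_requested_fwhm():
    fs, fwhm = 20.0, 0.5
    x = np.zeros(81)
    x[40] = 1.0
    out = smooth_timecourse(x, fs=fs, fwhm=fwhm)
    half = out.max() / 2
    width = np.sum(out >= half) / fs
    assert abs(width - fwhm) <= 1.5 / fs


def test_2d_smoothing_separable_and_constant_preserving():
    x = np.full((40, 40), -1.2)
    assert np.allclose(smooth_grid(x, fs=20.0, fwhm=0.1), -1.2, atol=1e-12)


def test_window_longer_than_axis_rejected():
    with pytest.raises(ValueError, match="shorter"):
        smooth_timecourse(np.zeros(5), fs=20.0, fwhm=0.5)


# ---------------------------------------------------------------------------
# model-level properties
# ---------------------------------------------------------------------------

def test_whitening_invariance_under_channel_transform(subject):
    """Any fixed invertible channel transform (noise re-estimated, no
    shrinkage) leaves D unchanged."""
    tensor, table, _ = subject
    rng = np.random.default_rng(8)
    A = rng.standard_normal((tensor.n_channels, tensor.n_channels))
    A += tensor.n_channels * np.eye(tensor.n_channels)  # well-conditioned
    transformed = tensor.copy_with(
        np.einsum("cd,idt->ict", A, tensor.data)
    )
    kw = dict(variables=("stimulus", "choice", "mapping"), reg=0.0)
    res1 = CrossValidatedMANOVA(tensor, table, **kw).fit(
        n_seeds=1, seed=0, smooth=False
    )
    res2 = CrossValidatedMANOVA(transformed, table, **kw).fit(
        n_seeds=1, seed=0, smooth=False
    )
    for v in ("stimulus", "choice"):
        scale = np.max(np.abs(res1[v]))
        assert np.max(np.abs(res1[v] - res2[v])) < 1e-6 * scale


def test_static_pattern_generalizes_across_time():
    """A temporally constant planted pattern yields a time × time matrix
    close to its diagonal value everywhere."""
    T = 30
    time = np.arange(T) / 20.0
    params = cheap_params(
        n_trials_per_task=200, time=time,
        patterns={"choice": 1.2},
        temporal_profiles={"choice": np.ones(T)},
        dv_gain=0.0, seed=21,
    )
    tensor, table, _ = simulate_subject(params)
    model = CrossValidatedMANOVA(
        tensor, table, variables=("stimulus", "choice", "mapping"),
        baseline_time=time[0],
    )
    res = model.fit(
        [Request(name="grid", train="choice", time_grid=True)],
        n_seeds=2, seed=0, smooth=False,
    )
    grid = res["grid"]
    diag = np.diagonal(grid).mean()
    assert diag > 0.2
    assert np.abs(grid - diag).max() < 0.5 * diag


def test_results_frame_and_summary(subject):
    tensor, table, _ = subject
    model = CrossValidatedMANOVA(tensor, table,
                                 variables=("stimulus", "choice", "mapping"))
    res = model.fit(n_seeds=1, seed=0)
    frame = res.to_frame()
    assert set(frame.columns) == {"request", "t_train", "t_test", "D"}
    assert len(frame) == 3 * tensor.n_time
    assert "choice" in res.summary()
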