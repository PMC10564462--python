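"""Signal conditioning: detrending, filtering, normalization, PCA."""

import numpy as np
import pytest

from cvdecode import (
    CrossValidatedMANOVA,
    TrialTensor,
    lowpass_downsample,
    normalize_runs,
    reduce_dimensions,
    robust_detrend,
    simulate_subject,
)
from conftest import cheap_params


def _tensor(data, fs, run=None):
    n, p, T = data.shape
    time = np.arange(T) / fs
    run = run if run is not None else np.array(["run1"] * n)
    return TrialTensor(data=data, time=time, fs=fs, run=run)


# ---------------------------------------------------------------------------
# robust detrending
# ---------------------------------------------------------------------------

def test_polynomial_trend_removes_itself():
    fs = 20.0
    t = np.linspace(-1, 1, 1200)
    coef = np.array([0.5, -1.0, 0.3, 0.2, -0.4, 0.1, 0.05, -0.02, 0.3, -0.1, 0.2])
    x = np.polynomial.polynomial.polyval(t, coef)
    out = robust_detrend(x, fs=fs, piece_length=600.0)
    assert np.max(np.abs(out)) < 1e-6 * np.max(np.abs(x))


def test_constant_signal_detrends_to_zero():
    out = robust_detrend(np.full(500, 7.7), fs=20.0)
    assert np.allclose(out, 0.0, atol=1e-9)


def test_spikes_survive_while_trend_goes():
    """Outlier down-weighting keeps sparse spikes out of the fit: the
    residual decorrelates from the trend while spikes keep amplitude
    (compared against a non-robust fit, which absorbs part of them)."""
    rng = np.random.default_rng(0)
    n, fs = 2000, 20.0
    t = np.linspace(-1, 1, n)
    trend = 5 * t**3 - 3 * t
    x = trend.copy()
    spike_ix = rng.choice(n, size=8, replace=False)
    x[spike_ix] += 40.0
    out = robust_detrend(x, fs=fs, piece_length=600.0, orders=(1, 10))
    corr = np.corrcoef(out, trend)[0, 1]
    assert abs(corr) < 0.05
    assert np.all(out[spike_ix] > 0.9 * 40.0)


def test_piece_too_short_rejected():
    with pytest.raises(ValueError, match="piece"):
        robust_detrend(np.zeros(8), fs=20.0, piece_length=0.2, orders=(1, 10))


def test_multichannel_detrend_matches_per_channel():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((3, 400)) + np.linspace(0, 5, 400)
    out = robust_detrend(x, fs=20.0)
    for ch in range(3):
        assert np.allclose(out[ch], robust_detrend(x[ch], fs=20.0))


# ---------------------------------------------------------------------------
# low-pass + downsample
# ---------------------------------------------------------------------------

def test_dc_passes_unchanged():
    data = np.full((2, 3, 400), 2.5)
    out = lowpass_downsample(_tensor(data, fs=200.0), cutoff=10.0, fs_out=20.0)
    assert np.allclose(out.data, 2.5, atol=1e-9)
    assert out.fs == 20.0
    assert out.data.shape[-1] == 40


def test_15hz_attenuated_by_20db():
    """1.5× the cutoff sits far down the two-pass order-4 Butterworth
    response: |H|⁴ there is ≈ −28 dB, so output RMS < 0.1 of input."""
    fs = 200.0
    t = np.arange(int(4 * fs)) / fs
    data = np.sin(2 * np.pi * 15.0 * t)[None, None, :]
    out = lowpass_downsample(_tensor(data, fs=fs), cutoff=10.0, fs_out=20.0)
    mid = out.data[0, 0, 10:-10]  # avoid filter edge transients
    assert np.sqrt(np.mean(mid**2)) < 0.1 * np.sqrt(0.5)


def test_filter_is_linear():
    rng = np.random.default_rng(2)
    x = _tensor(rng.standard_normal((2, 2, 300)), fs=100.0)
    y = _tensor(rng.standard_normal((2, 2, 300)), fs=100.0)
    combo = _tensor(2.0 * x.data - 3.0 * y.data, fs=100.0)
    fx = lowpass_downsample(x, 10.0, 20.0).data
    fy = lowpass_downsample(y, 10.0, 20.0).data
    fc = lowpass_downsample(combo, 10.0, 20.0).data
    assert np.allclose(fc, 2.0 * fx - 3.0 * fy, atol=1e-9)


def test_invalid_rates_rejected():
    data = np.zeros((1, 1, 100))
    with pytest.raises(ValueError, match="Nyquist"):
        lowpass_downsample(_tensor(data, fs=100.0), cutoff=15.0, fs_out=20.0)
    with pytest.raises(ValueError, match="integer"):
        lowpass_downsample(_tensor(data, fs=100.0), cutoff=10.0, fs_out=30.0)


# ---------------------------------------------------------------------------
# per-run normalization
# ---------------------------------------------------------------------------

def test_normalized_cells_have_zero_mean_unit_sd():
    rng = np.random.default_rng(3)
    run = np.array(["a"] * 10 + ["b"] * 14)
    data = rng.standard_normal((24, 3, 5)) + 5.0
    out = normalize_runs(_tensor(data, fs=20.0, run=run))
    for r in ("a", "b"):
        block = out.data[run == r]
        assert np.allclose(block.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(block.std(axis=0), 1.0, atol=1e-12)


def test_single_run_equals_global_zscore():
    rng = np.random.default_rng(4)
    data = rng.standard_normal((12, 2, 4))
    out = normalize_runs(_tensor(data, fs=20.0))
    expect = (data - data.mean(axis=0)) / data.std(axis=0)
    assert np.allclose(out.data, expect, atol=1e-12)


def test_between_run_offsets_removed_condition_sign_kept():
    """Run offsets vanish; a planted within-run condition difference keeps
    its sign after normalization."""
    rng = np.random.default_rng(5)
    n_half = 20
    run = np.array(["a"] * n_half + ["b"] * n_half)
    cond = np.tile([1.0, -1.0], n_half)  # balanced within runs
    data = rng.standard_normal((2 * n_half, 1, 3))
    data += cond[:, None, None] * 0.8           # condition effect
    data[run == "b"] += 50.0                     # run offset
    out = normalize_runs(_tensor(data, fs=20.0, run=run))
    for r in ("a", "b"):
        assert abs(out.data[run == r].mean()) < 1e-9
    diff = out.data[cond > 0].mean() - out.data[cond < 0].mean()
    assert diff > 0


def test_zero_variance_cell_identified():
    data = np.random.default_rng(6).standard_normal((8, 2, 3))
    data[:, 1, 2] = 4.2
    with pytest.raises(ValueError, match="channel 1, time index 2"):
        normalize_runs(_tensor(data, fs=20.0))


# ---------------------------------------------------------------------------
# dimensionality reduction
# ---------------------------------------------------------------------------

def test_full_rank_projection_preserves_distinctness():
    """k = channels is an invertible rotation: downstream D (with matched
    noise estimate, no shrinkage) is unchanged within 1e-6."""
    tensor, table, _ = simulate_subject(cheap_params(seed=31))
    reduced = reduce_dimensions(tensor, k=tensor.n_channels)
    kw = dict(variables=("stimulus", "choice", "mapping"), reg=0.0)
    res1 = CrossValidatedMANOVA(tensor, table, **kw).fit(n_seeds=1, smooth=False)
    res2 = CrossValidatedMANOVA(reduced, table, **kw).fit(n_seeds=1, smooth=False)
    scale = np.max(np.abs(res1["choice"]))
    assert np.max(np.abs(res1["choice"] - res2["choice"])) < 1e-6 * scale


def test_low_rank_data_reconstructs_exactly():
    rng = np.random.default_rng(7)
    basis = rng.standard_normal((3, 8))
    weights = rng.standard_normal((10, 3, 6))
    data = np.einsum("nkt,kp->npt", weights, basis)
    reduced = reduce_dimensions(_tensor(data, fs=20.0), k=3)
    # all variance captured: projection back spans the same subspace
    assert reduced.data.shape[1] == 3
    total = np.var(data.transpose(0, 2, 1).reshape(-1, 8).sum())  # noqa: F841
    flat = data.transpose(0, 2, 1).reshape(-1, 8)
    flat = flat - flat.mean(0)
    red = reduced.data.transpose(0, 2, 1).reshape(-1, 3)
    red = red - red.mean(0)
    assert np.isclose(np.sum(red**2), np.sum(flat**2), rtol=1e-9)
    with pytest.raises(ValueError, match="rank"):
        reduce_dimensions(_tensor(data, fs=20.0), k=5)


def test_pattern_in_discarded_components_loses_information():
    """A pattern carried by low-variance directions disappears after PCA,
    while one in the retained subspace survives."""
    rng = np.random.default_rng(8)
    n, T = 240, 12
    choice = np.tile([1.0, -1.0], n // 2)
    big = rng.standard_normal((n, 3, T)) * 5.0          # high-variance dims
    small = rng.standard_normal((n, 3, T)) * 0.2        # low-variance dims
    tiny_pattern = 1.0 * choice[:, None, None] * np.ones((1, 1, T))
    data_lost = np.concatenate([big, small + tiny_pattern], axis=1)
    data_kept = np.concatenate([big + tiny_pattern, small], axis=1)
    import pandas as pd

    table = pd.DataFrame({
        "stimulus": np.where(rng.random(n) < 0.5, "signal", "noise"),
        "choice": np.where(choice > 0, "yes", "no"),
        "run": "run1",
    })
    out = {}
    for name, data in (("lost", data_lost), ("kept", data_kept)):
        reduced = reduce_dimensions(_tensor(data, fs=20.0), k=3)
        model = CrossValidatedMANOVA(
            reduced, table, variables=("stimulus", "choice"),
            baseline_time=0.0,
        )
        out[name] = model.fit(n_seeds=2, smooth=False)["choice"].mean()
    assert out["kept"] > 5 * max(out["lost"], 1e-6)
    assert abs(out["lost"]) < 0.1 * out["kept"]
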