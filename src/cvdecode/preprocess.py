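"""Signal conditioning: robust detrending, zero-phase low-pass filtering
with downsampling, per-run normalization and PCA dimensionality reduction.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .containers import TrialTensor

__all__ = [
    "robust_detrend",
    "lowpass_downsample",
    "normalize_runs",
    "reduce_dimensions",
]


def _robust_polyfit_subtract(x: np.ndarray, order: int, max_iter: int = 3) -> np.ndarray:
    """Subtract a least-squares polynomial fit with outlier down-weighting.

    Samples whose residual exceeds 3 robust SDs (1.4826·MAD) are masked and
    the fit repeated, at most ``max_iter`` times, so sparse large deviations
    (spikes) do not drag the trend estimate.
    """
    t = np.linspace(-1.0, 1.0, x.size)
    mask = np.ones(x.size, dtype=bool)
    fit = np.zeros_like(x)
    for _ in range(max_iter):
        coef = np.polynomial.polynomial.polyfit(t[mask], x[mask], order)
        fit = np.polynomial.polynomial.polyval(t, coef)
        resid = x - fit
        mad = np.median(np.abs(resid[mask] - np.median(resid[mask])))
        sd = 1.4826 * mad
        if sd == 0:
            break
        new_mask = np.abs(resid) <= 3.0 * sd
        if new_mask.sum() <= order:
            break
        if np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return x - fit


def robust_detrend(
    series: np.ndarray,
    fs: float,
    piece_length: float = 600.0,
    orders: tuple[int, ...] = (1, 10),
) -> np.ndarray:
    """Piecewise robust polynomial detrending of a continuous signal.

    ``series`` is 1D (samples) or 2D (channels × samples). The signal is cut
    into pieces of ``piece_length`` seconds (processed independently); per
    piece, each polynomial order in ``orders`` is fitted in sequence with
    outlier down-weighting and subtracted — by default a linear trend
    followed by a 10th-order polynomial.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float)).copy()
    n = x.shape[1]
    piece = max(int(round(piece_length * fs)), 1)
    starts = list(range(0, n, piece))
    # merge a short trailing remainder into the previous piece
    if len(starts) > 1 and n - starts[-1] < max(orders) + 1:
        starts.pop()
    for s in starts:
        e = min(s + piece, n) if s != starts[-1] else n
        if e - s < max(orders) + 1:
            raise ValueError(
                f"piece [{s}:{e}] has {e - s} samples, fewer than "
                f"max(order)+1 = {max(orders) + 1}"
            )
        for ch in range(x.shape[0]):
            for order in orders:
                x[ch, s:e] = _robust_polyfit_subtract(x[ch, s:e], order)
    return x[0] if np.asarray(series).ndim == 1 else x


def lowpass_downsample(
    tensor: TrialTensor, cutoff: float = 10.0, fs_out: float = 20.0
) -> TrialTensor:
    """Zero-phase order-4 Butterworth low-pass, then integer decimation.

    Defaults follow the analysis convention of filtering at 10 Hz and
    resampling to 20 Hz. The forward–reverse pass doubles the effective
    filter order and cancels phase delay; decimation requires ``fs/fs_out``
    to be an integer so results are bit-reproducible.
    """
    fs = tensor.fs
    if cutoff > fs_out / 2:
        raise ValueError("cutoff must not exceed the output Nyquist rate")
    if not fs_out <= fs:
        raise ValueError("output rate cannot exceed input rate")
    factor = fs / fs_out
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(f"fs/fs_out = {factor} is not an integer")
    factor = int(round(factor))
    sos = scipy.signal.butter(4, cutoff, btype="low", fs=fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, tensor.data, axis=-1)
    data = filtered[..., ::factor]
    time = tensor.time[::factor]
    return tensor.copy_with(np.ascontiguousarray(data), time=time, fs=fs_out)


def normalize_runs(tensor: TrialTensor) -> TrialTensor:
    """Z-score each (channel, time) cell over trials, separately per run.

    Removes between-run offset and gain differences while preserving
    within-run condition structure. Fails on zero-variance cells, naming the
    run/channel/time location.
    """
    data = tensor.data.copy()
    for r in np.unique(tensor.run):
        idx = np.flatnonzero(tensor.run == r)
        if idx.size < 2:
            raise ValueError(f"run {r!r} has fewer than 2 trials")
        block = data[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=0)
        zero = np.argwhere(sd == 0)
        if zero.size:
            ch, t = zero[0]
            raise ValueError(
                f"zero variance over trials in run {r!r}, channel {ch}, "
                f"time index {t}"
            )
        data[idx] = (block - mu) / sd
    return tensor.copy_with(data)


def reduce_dimensions(tensor: TrialTensor, k: int = 75) -> TrialTensor:
    """Project onto the ``k`` leading principal directions of the pooled data.

    The projection is computed once from the trial × time concatenation over
    all conditions and applied to every time point, mirroring a
    whole-epoch PCA across all combinations of task variables.
    """
    n, p, T = tensor.data.shape
    if k > p:
        raise ValueError(f"k={k} exceeds channel count {p}")
    flat = tensor.data.transpose(0, 2, 1).reshape(n * T, p)
    flat = flat - flat.mean(axis=0)
    _, s, Vt = np.linalg.svd(flat, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds data rank {rank}")
    W = Vt[:k]
    data = np.einsum("kp,npt->nkt", W, tensor.data)
    out = tensor.copy_with(data)
    if tensor.channel_pos is not None:
        out.channel_pos = None
    return out
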