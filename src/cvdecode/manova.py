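"""Cross-validated MANOVA: noise-normalized pattern distinctness with
cross-variable, cross-temporal and cross-condition generalization.

The statistic
-------------
For a training and a test fold, per-condition response patterns are estimated
by least squares (``B = X⁺ Y``, the condition means under an indicator
design). A contrast ``C`` over unique conditions isolates one variable's main
effect; applying it to the betas yields the channel-space pattern difference
``δ = C'B``. Pattern distinctness is the cross-validated, noise-whitened dot
product of the training and test pattern differences,

    D = (g / n_test) · (C_train' B_train) Σ⁻¹ (C_test' B_test)'

with the design-dependent scale

    g = sqrt( (C_train' X'X C_train)(C_test' X'X C_test) )
        / ( (C_train' C_train)(C_test' C_test) ),

where ``X'X`` is the test fold's condition-count matrix. When the two
contrasts coincide this is algebraically identical to the trace form
``tr(B' P X'X P B Σ⁻¹)/n`` with ``P = C(C'C)⁺C'`` — the standard
cross-validated MANOVA statistic; for distinct contrasts the geometric-mean
scale keeps cross- and within-decoding values directly comparable. Because
training and test estimates come from independent data, D is unbiased under
the null and may legitimately be negative.

Σ⁻¹ is estimated from baseline-time residuals of the training fold, shrunk
toward a scaled identity and rescaled by ``fE − p − 1`` so that the product
with the sample precision is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TrialTensor
from .design import DesignSpec, assign_folds, build_design, subset_contrast

__all__ = [
    "NoisePrecision",
    "estimate_noise_precision",
    "fit_betas",
    "pattern_distinctness",
    "expected_cross",
    "hann_kernel",
    "smooth_timecourse",
    "smooth_grid",
    "Request",
    "CrossValidatedMANOVA",
    "DistinctnessResults",
    "decode",
]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

@dataclass
class NoisePrecision:
    """Regularized inverse noise covariance from baseline residuals."""

    precision: np.ndarray     # p × p, symmetric positive definite
    residuals: np.ndarray     # n × p baseline residuals Ξ
    fE: int                   # error degrees of freedom
    p: int                    # channel count
    lam: float                # shrinkage weight toward scaled identity


def estimate_noise_precision(
    baseline: np.ndarray, X: np.ndarray, lam: float = 0.05
) -> NoisePrecision:
    """Estimate Σ⁻¹ from baseline-time data of one training fold.

    Residuals after removing condition means are formed into ``S = Ξ'Ξ``,
    shrunk as ``(1−λ)·S + λ·(tr(S)/p)·I`` and inverted; the factor
    ``fE − p − 1`` makes ``E[Σ̂⁻¹]`` the population precision under
    Gaussian noise, which keeps the downstream distinctness unbiased.
    """
    Y = np.asarray(baseline, dtype=float)
    n, p = Y.shape
    rank = np.linalg.matrix_rank(X)
    fE = n - rank
    if fE <= p + 1:
        raise ValueError(
            f"noise estimation needs fE = n_train − rank(X) > p + 1; "
            f"got fE={fE} with p={p} (need at least {rank + p + 2} trials)"
        )
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Xi = Y - X @ B
    S = Xi.T @ Xi
    S_reg = (1.0 - lam) * S + lam * (np.trace(S) / p) * np.eye(p)
    precision = (fE - p - 1) * np.linalg.inv(S_reg)
    precision = 0.5 * (precision + precision.T)
    return NoisePrecision(precision=precision, residuals=Xi, fE=fE, p=p, lam=lam)


def fit_betas(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares condition coefficients ``B`` (q × channels).

    With an indicator design this is the per-condition trial mean. Fails on
    a rank-deficient design, naming unidentifiable (empty) conditions.
    """
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        empty = np.flatnonzero(np.abs(X).sum(axis=0) == 0)
        raise ValueError(
            f"design matrix is rank deficient; conditions {empty.tolist()} "
            "have no trials in this fold"
        )
    B, *_ = np.linalg.lstsq(X, np.asarray(Y, dtype=float), rcond=None)
    return B


def _design_scale(c_train, c_test, counts_test) -> float:
    qa = float(np.sum(counts_test * c_train * c_train))
    qb = float(np.sum(counts_test * c_test * c_test))
    return np.sqrt(qa * qb) / (float(c_train @ c_train) * float(c_test @ c_test))


def pattern_distinctness(
    B_train: np.ndarray,
    B_test: np.ndarray,
    X_test: np.ndarray,
    c_train: np.ndarray,
    c_test: np.ndarray,
    precision: np.ndarray,
    n_test: int,
) -> float:
    """Distinctness D for one train/test beta pair at fixed time points."""
    c_train = np.asarray(c_train, float)
    c_test = np.asarray(c_test, float)
    if not np.any(c_train) or not np.any(c_test):
        raise ValueError("contrast vector is identically zero")
    counts = np.einsum("nq,nq->q", X_test, X_test)
    g = _design_scale(c_train, c_test, counts)
    delta_train = c_train @ B_train
    delta_test = c_test @ B_test
    return g / n_test * float(delta_train @ precision @ delta_test)


def expected_cross(D1, D2):
    """Expected cross-decoding if two representations share one pattern.

    ``E12 = sqrt(|D1·D2|) · sign(D1) · sign(D2)`` — the geometric mean of the
    two within-context distinctness values, with the sign product carried
    outside the root so the formula extends continuously to (legitimately)
    negative inputs.
    """
    D1 = np.asarray(D1, dtype=float)
    D2 = np.asarray(D2, dtype=float)
    out = np.sqrt(np.abs(D1 * D2)) * np.sign(D1) * np.sign(D2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def hann_kernel(fwhm: float, fs: float) -> np.ndarray:
    """Unit-sum Hann kernel with the given full width at half maximum (s)."""
    half = int(round(fwhm * fs))
    if half < 1:
        return np.ones(1)
    w = np.hanning(2 * half + 1)
    return w / w.sum()


def smooth_timecourse(x: np.ndarray, fs: float, fwhm: float, axis: int = -1) -> np.ndarray:
    """Convolve along ``axis`` with a unit-sum Hann kernel; edges are
    renormalized over the kernel's valid support so a constant input is
    returned unchanged."""
    k = hann_kernel(fwhm, fs)
    if k.size >= x.shape[axis]:
        raise ValueError("smoothing window must be shorter than the time axis")
    if k.size == 1:
        return np.asarray(x, float).copy()

    def conv(v):
        num = np.convolve(v, k, mode="same")
        den = np.convolve(np.ones_like(v), k, mode="same")
        return num / den

    return np.apply_along_axis(conv, axis, np.asarray(x, float))


def smooth_grid(x: np.ndarray, fs: float, fwhm: float) -> np.ndarray:
    """Separable 2D Hann smoothing of a time × time generalization matrix."""
    out = smooth_timecourse(x, fs, fwhm, axis=-1)
    return smooth_timecourse(out, fs, fwhm, axis=-2)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

@dataclass
class Request:
    """One decoding request.

    ``train``/``test`` name a variable (its balanced main-effect contrast) or
    give an explicit contrast vector over unique conditions. ``test`` defaults
    to the training side; subsets restrict a contrast to conditions matching
    the given variable levels (e.g. ``{"task": "pre"}``). ``time_grid``
    requests a full train-time × test-time generalization matrix; otherwise
    only matched time points are computed. For asymmetric requests both
    train/test role assignments are evaluated and averaged unless
    ``symmetric=False``.
    """

    name: str
    train: str | np.ndarray = "choice"
    test: str | np.ndarray | None = None
    train_subset: dict[str, str] | None = None
    test_subset: dict[str, str] | None = None
    time_grid: bool = False
    symmetric: bool = True


class CrossValidatedMANOVA:
    """Time-resolved cross-validated MANOVA over a factorial trial design.

    Parameters
    ----------
    tensor
        Preprocessed trial data (trials × channels × time).
    table
        Per-trial condition table.
    variables
        Variables included in the model; information about each is estimated
        independently of all others because the design enumerates their
        unique combinations.
    reg
        Shrinkage weight of the baseline noise covariance toward a scaled
        identity (default 0.05).
    baseline_time
        Time (s) whose samples provide the noise estimate; default −0.5 s,
        before the first cue.
    """

    def __init__(
        self,
        tensor: TrialTensor,
        table: pd.DataFrame,
        variables=("task", "stimulus", "choice", "response", "mapping", "accuracy"),
        reg: float = 0.05,
        baseline_time: float = -0.5,
    ) -> None:
        if len(table) != tensor.n_trials:
            raise ValueError("condition table and tensor disagree on trial count")
        self.tensor = tensor
        self.table = table.reset_index(drop=True)
        self.spec: DesignSpec = build_design(self.table, variables)
        self.reg = reg
        self.baseline_time = baseline_time

    # -- internals ----------------------------------------------------------
    def _contrast(self, side, subset) -> np.ndarray:
        if isinstance(side, str):
            return subset_contrast(self.spec, side, subset)
        c = np.asarray(side, dtype=float)
        if c.shape != (self.spec.q,):
            raise ValueError("explicit contrast has wrong length")
        return c

    def fold_fits(self, fold_seed: int):
        """Yield per-fold quantities: (train_idx, test_idx, B_train, B_test,
        precision, test_condition_counts). Betas have shape (q, p, T)."""
        spec = self.spec
        folds = assign_folds(self.table, spec, fold_seed, self.tensor.n_channels)
        data = self.tensor.data
        bi = self.tensor.time_index(self.baseline_time)
        for k in range(folds.n_folds):
            tr, te = folds.train_indices(k), folds.test_indices(k)
            B_tr = _indicator_betas(data[tr], spec.condition_index[tr], spec.q)
            B_te = _indicator_betas(data[te], spec.condition_index[te], spec.q)
            noise = estimate_noise_precision(
                data[tr][:, :, bi], self.spec.X[tr], self.reg
            )
            counts_te = np.bincount(spec.condition_index[te], minlength=spec.q)
            yield tr, te, B_tr, B_te, noise.precision, counts_te

    def _request_D(self, request: Request, B_tr, B_te, P, counts_te, n_te):
        c_a = self._contrast(request.train, request.train_subset)
        test_side = request.train if request.test is None else request.test
        test_subset = (
            request.train_subset if request.test is None else request.test_subset
        )
        c_b = self._contrast(test_side, test_subset)
        if not np.any(c_a) or not np.any(c_b):
            raise ValueError("contrast vector is identically zero")

        def one(ca, cb):
            g = _design_scale(ca, cb, counts_te)
            a = np.einsum("q,qpt->pt", ca, B_tr)
            b = np.einsum("q,qpt->pt", cb, B_te)
            if request.time_grid:
                return g / n_te * (a.T @ P @ b)
            return g / n_te * np.einsum("pt,pr,rt->t", a, P, b)

        D = one(c_a, c_b)
        if request.symmetric and not np.array_equal(c_a, c_b):
            D = 0.5 * (D + one(c_b, c_a))
        return D

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        requests: list[Request] | None = None,
        n_seeds: int = 10,
        seed: int = 0,
        smooth: bool = True,
        fwhm_1d: float = 0.5,
        fwhm_2d: float = 0.1,
    ) -> "DistinctnessResults":
        """Estimate pattern distinctness for each request.

        D is averaged over cross-validation folds, both train/test direction
        assignments of asymmetric requests, and ``n_seeds`` random fold
        partitions, then smoothed with unit-sum Hann kernels (500 ms FWHM for
        time courses, 100 ms for time × time grids).
        """
        if requests is None:
            requests = [Request(name=v, train=v) for v in self.spec.variables]
        rng = np.random.default_rng(seed)
        fold_seeds = rng.integers(2**31 - 1, size=n_seeds)
        sums: dict[str, np.ndarray] = {}
        n_terms = 0
        n_folds = None
        for fs_ in fold_seeds:
            fold_count = 0
            for tr, te, B_tr, B_te, P, counts_te in self.fold_fits(int(fs_)):
                fold_count += 1
                n_terms += 1
                for req in requests:
                    D = self._request_D(req, B_tr, B_te, P, counts_te, te.size)
                    if req.name in sums:
                        sums[req.name] += D
                    else:
                        sums[req.name] = np.array(D, dtype=float)
            n_folds = fold_count
        estimates = {k: v / n_terms for k, v in sums.items()}
        if smooth:
            for req in requests:
                est = estimates[req.name]
                if req.time_grid:
                    estimates[req.name] = smooth_grid(est, self.tensor.fs, fwhm_2d)
                elif est.size > hann_kernel(fwhm_1d, self.tensor.fs).size:
                    estimates[req.name] = smooth_timecourse(
                        est, self.tensor.fs, fwhm_1d
                    )
        return DistinctnessResults(
            estimates=estimates,
            requests={r.name: r for r in requests},
            time=self.tensor.time,
            n_folds=n_folds,
            n_seeds=n_seeds,
            smoothed=smooth,
            model=self,
        )


def _indicator_betas(data: np.ndarray, cond_index: np.ndarray, q: int) -> np.ndarray:
    """Per-condition mean patterns, shape (q, p, T)."""
    n, p, T = data.shape
    sums = np.zeros((q, p * T))
    np.add.at(sums, cond_index, data.reshape(n, p * T))
    counts = np.bincount(cond_index, minlength=q).astype(float)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise ValueError(f"conditions {empty.tolist()} have no trials in this fold")
    return (sums / counts[:, None]).reshape(q, p, T)


@dataclass
class DistinctnessResults:
    """Fold/direction/seed-averaged pattern distinctness per request.

    ``estimates[name]`` is a time course (T,) or a train-time × test-time
    matrix (T, T) for ``time_grid`` requests. Distinctness is unitless and
    unbiased under the null, so values scatter around zero in the absence of
    an effect.
    """

    estimates: dict[str, np.ndarray]
    requests: dict[str, Request]
    time: np.ndarray
    n_folds: int
    n_seeds: int
    smoothed: bool
    model: CrossValidatedMANOVA | None = field(default=None, repr=False)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.estimates[name]

    def expected_cross(self, name1: str, name2: str):
        """E12 from the two named within-context time courses."""
        return expected_cross(self.estimates[name1], self.estimates[name2])

    def window_mean(self, name: str, window: tuple[float, float]) -> float:
        lo, hi = window
        m = (self.time >= lo) & (self.time <= hi)
        return float(np.mean(self.estimates[name][..., m]))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table (one row per estimate cell)."""
        rows = []
        for name, est in self.estimates.items():
            req = self.requests[name]
            if est.ndim == 1:
                for t, d in zip(self.time, est):
                    rows.append(
                        dict(request=name, t_train=t, t_test=t, D=d)
                    )
            else:
                for i, t1 in enumerate(self.time):
                    for j, t2 in enumerate(self.time):
                        rows.append(
                            dict(request=name, t_train=t1, t_test=t2, D=est[i, j])
                        )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Cross-validated MANOVA pattern distinctness",
            f"  folds: {self.n_folds}   seed repetitions: {self.n_seeds}"
            f"   smoothed: {self.smoothed}",
            f"  {'request':<28}{'peak D':>10}{'peak t (s)':>12}{'mean D':>10}",
        ]
        for name, est in self.estimates.items():
            flat = est if est.ndim == 1 else np.diagonal(est)
            i = int(np.argmax(flat))
            lines.append(
                f"  {name:<28}{flat[i]:>10.4f}{self.time[i]:>12.2f}"
                f"{flat.mean():>10.4f}"
            )
        return "\n".join(lines)

    def plot(self, names=None, ax=None):
        """Plot distinctness time courses (matplotlib axes returned)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in names or self.estimates:
            est = self.estimates[name]
            if est.ndim == 1:
                ax.plot(self.time, est, label=name)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("pattern distinctness D")
        ax.legend()
        return ax

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def decode(
    tensor: TrialTensor,
    table: pd.DataFrame,
    variables,
    requests: list[Request] | None = None,
    n_seeds: int = 10,
    seed: int = 0,
    **fit_kw,
) -> DistinctnessResults:
    """Convenience wrapper: build the model and fit in one call."""
    model = CrossValidatedMANOVA(tensor, table, variables=variables)
    return model.fit(requests, n_seeds=n_seeds, seed=seed, **fit_kw)
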