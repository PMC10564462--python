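"""Synthetic subjects for a flexible sensorimotor detection task.

Generates trial-wise behavior and multichannel "source-level" time series
with the statistical structure the decoding analysis assumes:

* a 2 × 2 × 2 controlled factorial core (task context pre/post, stimulus
  signal/noise, choice–response mapping), balanced by construction;
* near-threshold detection behavior from an equal-variance signal-detection
  model: a scalar decision variable ``DV = prior + effect·1[signal] +
  sequential bias + N(0,1)`` determines choice (``DV > criterion``) and
  confidence (``|DV − criterion| > threshold``) exactly, so accuracy and
  response follow deterministically;
* planted multivariate patterns per variable — unit channel vectors with
  exactly controlled pairwise angles, modulated by per-variable temporal
  envelopes — embedded in spatially correlated Gaussian noise. The choice
  pattern's amplitude can additionally scale with the distance of the DV
  from the decision boundary, which couples neural choice-signal strength
  to confidence and accuracy.

The module also provides a brute-force Monte-Carlo oracle for the expected
value of the distinctness estimator under a planted configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import TrialTensor, accuracy_from, response_from

_CONTEXT_PATTERNS = {"choice_pre": "choice", "choice_post": "choice"}


def _pattern_variable(name: str) -> str:
    """Variable a pattern name modulates ('choice_pre' -> 'choice')."""
    return _CONTEXT_PATTERNS.get(name, name)


@dataclass
class GeneratorParams:
    """Parameters of the synthetic subject generator.

    Defaults emulate the study conditions: 240 trials per task context over
    2 runs, 75 channels, a −1.0…6.5 s epoch at 20 Hz, and a latent
    sensitivity of 1.35 with an unbiased criterion, which yields ≈74%
    correct with roughly balanced left/right responses.
    """

    n_trials_per_task: int = 240
    n_channels: int = 75
    time: np.ndarray | None = None          # default −1.0…6.5 s at 20 Hz
    fs: float = 20.0
    n_runs: int = 2
    stimulus_effect: float = 1.35           # latent d′ (evidence SD = 1)
    criterion: float = 0.675                # unbiased: stimulus_effect / 2
    confidence_threshold: float = 0.8       # |DV − criterion| cutoff
    prior_sd: float = 0.2                   # pre-stimulus bias dispersion
    sequential_weight: float = 0.2          # previous-choice pull on the DV
    sequential_mode: str = "magnitude"      # 'magnitude' or 'signed'
    patterns: dict[str, float] = field(
        default_factory=lambda: {"stimulus": 1.0, "choice": 1.0, "response": 1.0}
    )
    overlap_angles: dict[tuple[str, str], float] = field(default_factory=dict)
    pattern_bank: dict[str, np.ndarray] | None = None
    temporal_profiles: dict[str, np.ndarray] | None = None
    dv_gain: float = 0.5                    # choice amplitude ∝ 1 + gain·|DV−c|
    noise_covariance_spec: dict = field(
        default_factory=lambda: {"kind": "exponential", "rho": 0.3, "sd": 1.0}
    )
    seed: int = 0

    def time_axis(self) -> np.ndarray:
        if self.time is not None:
            return np.asarray(self.time, dtype=float)
        n = int(round((6.5 - (-1.0)) * self.fs)) + 1
        return -1.0 + np.arange(n) / self.fs


@dataclass
class GroundTruth:
    """Latent quantities of one simulated subject (oracle for tests)."""

    dv: np.ndarray                          # per-trial decision variable
    patterns: dict[str, np.ndarray]         # unit channel vectors
    amplitudes: dict[str, np.ndarray]       # per-pattern envelope over time
    realized_accuracy: float
    criterion: float

    def to_json_dict(self) -> dict:
        return {
            "dv": self.dv.tolist(),
            "patterns": {k: v.tolist() for k, v in self.patterns.items()},
            "amplitudes": {k: v.tolist() for k, v in self.amplitudes.items()},
            "realized_accuracy": self.realized_accuracy,
            "criterion": self.criterion,
        }


def default_profiles(time: np.ndarray) -> dict[str, np.ndarray]:
    """Per-variable amplitude envelopes over the trial epoch.

    Onsets follow the trial structure (first cue at 0 s, stimulus at
    1.25–3.25 s, go-cue near 5.5 s): task and mapping information from the
    first cue, stimulus information during presentation, choice information
    ramping up during the stimulus and persisting, response information late.
    """
    t = np.asarray(time, dtype=float)

    def ramp(on, rise=0.25, off=None, fall=0.25):
        y = np.clip((t - on) / rise, 0.0, 1.0)
        if off is not None:
            y = y * np.clip((off - t) / fall + 1.0, 0.0, 1.0)
        return y

    choice = ramp(1.25, rise=1.0)
    return {
        "task": ramp(0.0),
        "mapping": ramp(0.0),
        "stimulus": ramp(1.25, off=3.25),
        "choice": choice,
        "choice_pre": choice,
        "choice_post": choice,
        "confidence": ramp(2.0, rise=1.0),
        "response": ramp(5.25),
        "prev_choice": np.ones_like(t),
        "prev_response": np.ones_like(t),
    }


def build_pattern_bank(
    names: list[str],
    n_channels: int,
    overlap_angles: dict[tuple[str, str], float],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Unit pattern vectors with exactly controlled pairwise angles.

    All patterns start mutually orthonormal (QR of a random Gaussian basis);
    each ``(a, b): θ`` entry then rotates ``b`` inside span(a, b) so the
    angle between ``a`` and ``b`` equals θ exactly. A name may appear as the
    second element of at most one pair.
    """
    if len(names) > n_channels:
        raise ValueError(
            f"{len(names)} patterns need at least that many channels; "
            f"got {n_channels}"
        )
    G = rng.standard_normal((n_channels, len(names)))
    Q, _ = np.linalg.qr(G)
    bank = {name: Q[:, i].copy() for i, name in enumerate(names)}
    rotated: set[str] = set()
    for (a, b), deg in overlap_angles.items():
        if a not in bank or b not in bank:
            continue
        if b in rotated:
            raise ValueError(f"pattern {b!r} is the target of multiple angle specs")
        theta = np.deg2rad(deg)
        bank[b] = np.cos(theta) * bank[a] + np.sin(theta) * Q[:, names.index(b)]
        rotated.add(b)
    return bank


def _noise_chol(spec: dict, p: int) -> np.ndarray:
    kind = spec.get("kind", "exponential")
    sd = float(spec.get("sd", 1.0))
    if sd <= 0:
        raise ValueError("noise standard deviation must be positive")
    if kind == "identity":
        K = np.eye(p)
    elif kind == "exponential":
        rho = float(spec.get("rho", 0.3))
        if not 0 <= rho < 1:
            raise ValueError("exponential noise correlation must be in [0, 1)")
        K = rho ** np.abs(np.subtract.outer(np.arange(p), np.arange(p)))
    elif kind == "matrix":
        K = np.asarray(spec["value"], dtype=float)
    else:
        raise ValueError(f"unknown noise covariance kind {kind!r}")
    return sd * np.linalg.cholesky(K)


def simulate_subject(
    params: GeneratorParams,
) -> tuple[TrialTensor, pd.DataFrame, GroundTruth]:
    """Simulate one subject: behavior, neural data and ground truth.

    Controlled factors (task, stimulus, mapping) are balanced exactly;
    behavioral factors (choice, response, accuracy, confidence) follow from
    the signal-detection decision variable. Neural data are the sum of the
    planted per-variable patterns, scaled by each trial's ±1 level code and
    the variable's temporal envelope, plus spatially correlated Gaussian
    noise. Determinism: identical params + seed give bit-identical output.
    """
    if params.n_trials_per_task < 64:
        raise ValueError("need at least 64 trials per task context")
    time = params.time_axis()
    if time.size < 2 or np.any(np.diff(time) <= 0):
        raise ValueError("time axis must be strictly increasing")
    fs = 1.0 / np.diff(time)[0]
    rng = np.random.default_rng(params.seed)
    n = 2 * params.n_trials_per_task
    p, T = params.n_channels, time.size

    # -- balanced controlled factors, randomly interleaved ------------------
    def balanced(levels):
        half = n // 2
        arr = np.array([levels[0]] * half + [levels[1]] * (n - half))
        return arr

    task = rng.permutation(balanced(("pre", "post")))
    stimulus = rng.permutation(balanced(("signal", "noise")))
    mapping = rng.permutation(balanced(("yes=left", "yes=right")))
    run = np.array([f"run{1 + (i * params.n_runs) // n}" for i in range(n)])

    for name, col, lv in (
        ("task", task, ("pre", "post")),
        ("stimulus", stimulus, ("signal", "noise")),
        ("mapping", mapping, ("yes=left", "yes=right")),
    ):
        for level in lv:
            if not np.any(col == level):
                raise ValueError(f"empty condition after draw: {name}={level}")

    # -- decision variable and behavioral cascade ---------------------------
    prior = rng.normal(0.0, params.prior_sd, size=n)
    evidence_noise = rng.standard_normal(n)
    seq_draw = rng.normal(0.0, params.sequential_weight, size=n) \
        if params.sequential_weight > 0 else np.zeros(n)
    if params.sequential_mode == "magnitude":
        seq_draw = np.abs(seq_draw)
    elif params.sequential_mode != "signed":
        raise ValueError("sequential_mode must be 'magnitude' or 'signed'")

    dv = np.empty(n)
    choice = np.empty(n, dtype=object)
    prev_choice = np.empty(n, dtype=object)
    prev_response = np.empty(n, dtype=object)
    last_choice_signed = 0.0
    last_choice: str | float = np.nan
    last_response: str | float = np.nan
    last_run = None
    for i in range(n):
        if run[i] != last_run:
            last_choice_signed, last_choice, last_response = 0.0, np.nan, np.nan
            last_run = run[i]
        dv[i] = (
            prior[i]
            + params.stimulus_effect * (stimulus[i] == "signal")
            + seq_draw[i] * last_choice_signed
            + evidence_noise[i]
        )
        prev_choice[i], prev_response[i] = last_choice, last_response
        choice[i] = "yes" if dv[i] > params.criterion else "no"
        last_choice_signed = 1.0 if choice[i] == "yes" else -1.0
        last_choice = choice[i]
        last_response = response_from(choice[i], mapping[i])

    for level in ("yes", "no"):
        if not np.any(choice == level):
            raise ValueError(f"empty condition after draw: choice={level}")

    confidence = np.where(
        np.abs(dv - params.criterion) > params.confidence_threshold, "high", "low"
    )
    response = np.array([response_from(c, m) for c, m in zip(choice, mapping)])
    accuracy = np.array([accuracy_from(s, c) for s, c in zip(stimulus, choice)])

    table = pd.DataFrame(
        {
            "task": task,
            "stimulus": stimulus,
            "choice": choice.astype(str),
            "response": response,
            "mapping": mapping,
            "accuracy": accuracy,
            "confidence": confidence,
            "prev_choice": prev_choice,
            "prev_response": prev_response,
            "run": run,
        }
    )

    # -- neural data --------------------------------------------------------
    profiles = dict(default_profiles(time))
    if params.temporal_profiles:
        profiles.update(
            {k: np.asarray(v, dtype=float) for k, v in params.temporal_profiles.items()}
        )
    names = list(params.patterns)
    if params.pattern_bank is not None:
        bank = {k: np.asarray(v, dtype=float) for k, v in params.pattern_bank.items()}
        for name in names:
            if name not in bank:
                raise ValueError(f"pattern_bank missing vector for {name!r}")
            nrm = np.linalg.norm(bank[name])
            if abs(nrm - 1.0) > 1e-9:
                raise ValueError(f"pattern {name!r} must have unit norm (got {nrm})")
    else:
        bank = build_pattern_bank(names, p, params.overlap_angles, rng)

    level_codes = {
        "task": (task == "pre"),
        "stimulus": (stimulus == "signal"),
        "choice": (choice == "yes"),
        "response": (response == "left"),
        "mapping": (mapping == "yes=left"),
        "accuracy": (accuracy == "correct"),
        "confidence": (confidence == "high"),
    }
    dv_scale = 1.0 + params.dv_gain * np.abs(dv - params.criterion)

    signal = np.zeros((n, p, T))
    amplitudes: dict[str, np.ndarray] = {}
    for name in names:
        var = _pattern_variable(name)
        amp = params.patterns[name]
        prof = profiles[name] if name in profiles else profiles[var]
        if prof.shape != time.shape:
            raise ValueError(f"temporal profile for {name!r} has wrong length")
        lv = np.where(level_codes[var], 1.0, -1.0)
        if name == "choice_pre":
            lv = lv * (task == "pre")
        elif name == "choice_post":
            lv = lv * (task == "post")
        if var == "choice":
            lv = lv * dv_scale
        amplitudes[name] = amp * prof
        signal += np.einsum("i,c,t->ict", lv, amp * bank[name], prof)

    L = _noise_chol(params.noise_covariance_spec, p)
    noise = np.einsum("cd,idt->ict", L, rng.standard_normal((n, p, T)))
    tensor = TrialTensor(data=signal + noise, time=time, fs=fs, run=run)

    truth = GroundTruth(
        dv=dv,
        patterns=bank,
        amplitudes=amplitudes,
        realized_accuracy=float(np.mean(accuracy == "correct")),
        criterion=params.criterion,
    )
    return tensor, table, truth


# ---------------------------------------------------------------------------
# Monte-Carlo oracle
# ---------------------------------------------------------------------------

def _naive_distinctness(
    data: np.ndarray, cond: np.ndarray, c: np.ndarray, baseline: np.ndarray,
    lam: float = 0.05,
) -> float:
    """Brute-force distinctness on one dataset: alternate trials per
    condition into two folds, per-condition means, explicit projector/trace
    formula, both fold directions averaged. Deliberately plain — this is the
    oracle, kept independent of the estimation path in :mod:`~cvdecode.manova`.
    """
    q = int(cond.max()) + 1
    n, p = data.shape
    fold = np.zeros(n, dtype=int)
    for j in range(q):
        idx = np.flatnonzero(cond == j)
        fold[idx[1::2]] = 1

    def half(which):
        idx = np.flatnonzero(fold == which)
        X = np.zeros((idx.size, q))
        X[np.arange(idx.size), cond[idx]] = 1.0
        B = np.stack([data[idx][cond[idx] == j].mean(axis=0) for j in range(q)])
        Ybl = baseline[idx]
        Xi = Ybl - X @ np.linalg.pinv(X) @ Ybl
        S = Xi.T @ Xi
        S = (1 - lam) * S + lam * np.trace(S) / p * np.eye(p)
        fE = idx.size - q
        P = (fE - p - 1) * np.linalg.inv(S)
        return X, B, P, idx.size

    C = c[:, None]
    proj = C @ np.linalg.pinv(C.T @ C) @ C.T
    out = []
    for a, b in ((0, 1), (1, 0)):
        Xa, Ba, Pa, _ = half(a)
        Xb, Bb, _, nb = half(b)
        H = Ba.T @ proj @ (Xb.T @ Xb) @ proj @ Bb
        out.append(np.trace(H @ Pa) / nb)
    return float(np.mean(out))


def oracle_distinctness(
    params: GeneratorParams,
    variable: str,
    t: float,
    n_reps: int = 1000,
    variables: tuple[str, ...] = ("stimulus", "choice"),
) -> float:
    """Monte-Carlo expectation of estimated distinctness for a planted
    configuration: simulates ``n_reps`` replicate subjects (small channel
    counts recommended) and averages a brute-force estimate at time ``t``.
    """
    vals = []
    for r in range(n_reps):
        rep = GeneratorParams(**{**params.__dict__, "seed": params.seed + 1 + r})
        tensor, table, _ = simulate_subject(rep)
        keys = table[list(variables)].apply(tuple, axis=1)
        uniq = sorted(set(keys))
        cond = np.array([uniq.index(k) for k in keys])
        iv = variables.index(variable)
        from .containers import LEVELS

        pos = np.array([u[iv] == LEVELS[variable][0] for u in uniq])
        c = np.where(pos, 1.0 / max(pos.sum(), 1), -1.0 / max((~pos).sum(), 1))
        ti = tensor.time_index(t)
        bi = tensor.time_index(-0.5)
        vals.append(
            _naive_distinctness(
                tensor.data[:, :, ti], cond, c, tensor.data[:, :, bi]
            )
        )
    return float(np.mean(vals))
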