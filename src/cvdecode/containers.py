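"""Core data containers: trial-wise time series and the per-trial condition table.

The analysis operates on a :class:`TrialTensor` (trials × channels × time) and
a pandas ``DataFrame`` condition table with one row per trial. The table's
categorical columns follow fixed level names (see :data:`LEVELS`); two of the
columns are deterministic functions of the others and are validated as such:

* ``accuracy`` is ``correct`` iff the choice matches the stimulus class,
* ``response`` is the image of ``(choice, mapping)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

#: Canonical binary levels per variable; the first entry is the positive level
#: in every contrast built by :mod:`cvdecode.design`.
LEVELS: dict[str, tuple[str, str]] = {
    "task": ("pre", "post"),
    "stimulus": ("signal", "noise"),
    "choice": ("yes", "no"),
    "response": ("left", "right"),
    "mapping": ("yes=left", "yes=right"),
    "accuracy": ("correct", "incorrect"),
    "confidence": ("high", "low"),
    "prev_choice": ("yes", "no"),
    "prev_response": ("left", "right"),
}

CONDITION_COLUMNS = [
    "task", "stimulus", "choice", "response", "mapping",
    "accuracy", "confidence", "prev_choice", "prev_response", "run",
]


def response_from(choice: str, mapping: str) -> str:
    """Deterministic mapping of a yes/no choice to a left/right response."""
    if mapping == "yes=left":
        return "left" if choice == "yes" else "right"
    return "right" if choice == "yes" else "left"


def accuracy_from(stimulus: str, choice: str) -> str:
    correct = (stimulus == "signal") == (choice == "yes")
    return "correct" if correct else "incorrect"


def validate_condition_table(table: pd.DataFrame) -> None:
    """Check the deterministic-dependency invariants of a condition table.

    Raises ``ValueError`` listing the offending trial indices if ``accuracy``
    or ``response`` is inconsistent with the variables that determine it.
    Columns that are absent are not checked.
    """
    cols = set(table.columns)
    if {"stimulus", "choice", "accuracy"} <= cols:
        expected = [
            accuracy_from(s, c) for s, c in zip(table["stimulus"], table["choice"])
        ]
        bad = np.flatnonzero(np.asarray(expected) != table["accuracy"].to_numpy())
        if bad.size:
            raise ValueError(
                "accuracy inconsistent with (stimulus, choice) at trials "
                f"{bad.tolist()[:20]}"
            )
    if {"choice", "mapping", "response"} <= cols:
        expected = [
            response_from(c, m) for c, m in zip(table["choice"], table["mapping"])
        ]
        bad = np.flatnonzero(np.asarray(expected) != table["response"].to_numpy())
        if bad.size:
            raise ValueError(
                "response inconsistent with (choice, mapping) at trials "
                f"{bad.tolist()[:20]}"
            )
    for var, levels in LEVELS.items():
        if var in cols:
            observed = set(table[var].dropna().unique())
            extra = observed - set(levels)
            if extra:
                raise ValueError(f"unknown level(s) {sorted(extra)} for {var!r}")


@dataclass
class TrialTensor:
    """Trial-wise multichannel time series.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_channels, n_time)``.
    time
        Time axis in seconds, strictly increasing and uniformly spaced.
    fs
        Sampling rate in Hz; must match the time-axis spacing.
    run
        Per-trial run label (length ``n_trials``).
    channel_pos
        Optional ``(n_channels, 3)`` source coordinates in mm, used by the
        searchlight analysis.
    """

    data: np.ndarray
    time: np.ndarray
    fs: float
    run: np.ndarray
    channel_pos: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.run = np.asarray(self.run)
        if self.data.ndim != 3:
            raise ValueError("data must be trials × channels × time")
        if self.data.shape[2] != self.time.size:
            raise ValueError("time axis length does not match data")
        if self.data.shape[0] != self.run.size:
            raise ValueError("run labels do not match trial count")
        dt = np.diff(self.time)
        if self.time.size > 1:
            if np.any(dt <= 0) or np.ptp(dt) > 1e-9:
                raise ValueError("time axis must be strictly increasing and uniform")
            if abs(dt[0] - 1.0 / self.fs) > 1e-9:
                raise ValueError("fs inconsistent with time-axis spacing")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_time(self) -> int:
        return self.data.shape[2]

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds)."""
        return int(np.argmin(np.abs(self.time - t)))

    def copy_with(self, data: np.ndarray, **kw) -> "TrialTensor":
        return TrialTensor(
            data=data,
            time=kw.get("time", self.time),
            fs=kw.get("fs", self.fs),
            run=kw.get("run", self.run),
            channel_pos=kw.get("channel_pos", self.channel_pos),
        )

    # -- HDF5 interchange ---------------------------------------------------
    def to_hdf5(self, path: str | Path) -> None:
        """Write datasets ``/data``, ``/time``, ``/run`` (and positions)."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("time", data=self.time)
            f.create_dataset("run", data=np.asarray(self.run, dtype="S"))
            f.attrs["fs"] = self.fs
            if self.channel_pos is not None:
                f.create_dataset("channel_pos", data=self.channel_pos)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "TrialTensor":
        with h5py.File(path, "r") as f:
            pos = f["channel_pos"][()] if "channel_pos" in f else None
            return cls(
                data=f["data"][()],
                time=f["time"][()],
                fs=float(f.attrs["fs"]),
                run=f["run"][()].astype(str),
                channel_pos=pos,
            )


def save_condition_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_condition_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"run": str})
    validate_condition_table(table)
    return table


def save_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
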