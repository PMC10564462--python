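"""Design matrices, main-effect contrasts and condition-balanced folds.

Every analysis is phrased over the *unique conditions*: the occupied
combinations of the included binary task variables (at most 32 in the full
factorial design). The trial design matrix ``X`` is a one-hot indicator of
each trial's condition, and a variable's contrast is a signed weighting over
conditions that isolates its main effect while staying balanced over all
other included variables.

Cross-validation folds are built so that *every* fold's training and test
sets contain at least one trial of every unique condition: the number of
folds equals the smallest per-condition trial count, and trials are dealt
into folds within each condition by a seeded shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import LEVELS, validate_condition_table

# variable -> the set of variables that deterministically fix it
_DETERMINED_BY = {
    "accuracy": {"stimulus", "choice"},
    "response": {"choice", "mapping"},
}


@dataclass
class DesignSpec:
    """Unique conditions, trial indicator matrix and per-variable contrasts."""

    variables: tuple[str, ...]
    unique_conditions: list[tuple[str, ...]]
    X: np.ndarray                      # trials × q indicator
    contrasts: dict[str, np.ndarray]   # variable -> q-vector
    condition_index: np.ndarray        # per-trial condition id

    @property
    def q(self) -> int:
        return len(self.unique_conditions)

    @property
    def n_independent(self) -> int:
        """Number of independent variables (K in the trial-count bound)."""
        k = len(self.variables)
        for var, parents in _DETERMINED_BY.items():
            if var in self.variables and parents <= set(self.variables):
                k -= 1
        return k

    def condition_mask(self, subset: dict[str, str]) -> np.ndarray:
        """Boolean mask over unique conditions matching ``subset`` levels."""
        mask = np.ones(self.q, dtype=bool)
        for var, level in subset.items():
            i = self.variables.index(var)
            mask &= np.array([c[i] == level for c in self.unique_conditions])
        return mask

    def to_json_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "unique_conditions": [list(c) for c in self.unique_conditions],
            "contrasts": {k: v.tolist() for k, v in self.contrasts.items()},
        }


def build_design(table: pd.DataFrame, variables: list[str] | tuple[str, ...]) -> DesignSpec:
    """Enumerate occupied conditions and build X and main-effect contrasts.

    Parameters
    ----------
    table
        Condition table with one row per trial; its deterministic
        dependencies are validated before anything is built.
    variables
        The binary variables included in the model. Each must have exactly
        two levels present in the data.
    """
    variables = tuple(variables)
    validate_condition_table(table)
    for var in variables:
        if var not in table.columns:
            raise ValueError(f"variable {var!r} not in table")
        levels = [l for l in table[var].dropna().unique()]
        if len(levels) != 2:
            raise ValueError(
                f"variable {var!r} must have exactly 2 levels present, got {levels}"
            )

    keys = table[list(variables)].apply(tuple, axis=1)
    unique_conditions = sorted(set(keys))
    cond_id = {c: j for j, c in enumerate(unique_conditions)}
    condition_index = np.array([cond_id[k] for k in keys])
    n, q = len(table), len(unique_conditions)
    X = np.zeros((n, q))
    X[np.arange(n), condition_index] = 1.0

    contrasts: dict[str, np.ndarray] = {}
    for i, var in enumerate(variables):
        pos_level = LEVELS[var][0]
        pos = np.array([c[i] == pos_level for c in unique_conditions])
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        c = np.where(pos, 1.0 / n_pos, -1.0 / n_neg)
        contrasts[var] = c

    return DesignSpec(
        variables=variables,
        unique_conditions=unique_conditions,
        X=X,
        contrasts=contrasts,
        condition_index=condition_index,
    )


def subset_contrast(
    spec: DesignSpec,
    variable: str,
    subset: dict[str, str] | None = None,
) -> np.ndarray:
    """Main-effect contrast of ``variable`` restricted to a condition subset.

    The contrast only weights conditions matching ``subset`` (e.g. the
    pre-cue context), rebalanced to ±1/n per level so it remains the
    difference of the two level-averaged condition means within the subset.
    """
    i = spec.variables.index(variable)
    mask = spec.condition_mask(subset) if subset else np.ones(spec.q, dtype=bool)
    pos_level = LEVELS[variable][0]
    pos = np.array([c[i] == pos_level for c in spec.unique_conditions]) & mask
    neg = np.array([c[i] != pos_level for c in spec.unique_conditions]) & mask
    if not pos.any() or not neg.any():
        missing = "positive" if not pos.any() else "negative"
        raise ValueError(
            f"subset {subset} empties the {missing} level of {variable!r}"
        )
    c = np.zeros(spec.q)
    c[pos] = 1.0 / pos.sum()
    c[neg] = -1.0 / neg.sum()
    return c


def cell_pair_contrast(
    spec: DesignSpec, cell_a: dict[str, str], cell_b: dict[str, str]
) -> np.ndarray:
    """Contrast between two arbitrary condition cells (cell_a minus cell_b)."""
    a = spec.condition_mask(cell_a)
    b = spec.condition_mask(cell_b)
    if not a.any() or not b.any():
        empty = cell_a if not a.any() else cell_b
        raise ValueError(f"cell {empty} matches no occupied condition")
    if (a & b).any():
        raise ValueError("cells overlap")
    c = np.zeros(spec.q)
    c[a] = 1.0 / a.sum()
    c[b] = -1.0 / b.sum()
    return c


@dataclass
class FoldAssignment:
    """Partition of trials into condition-balanced cross-validation folds."""

    fold_id: np.ndarray
    n_folds: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != fold)


def assign_folds(
    table: pd.DataFrame,
    spec: DesignSpec,
    seed: int,
    n_channels: int,
) -> FoldAssignment:
    """Assign trials to folds; the fold count is the lowest condition count.

    Within each unique condition, trials are shuffled (seeded) and dealt
    round-robin across folds, so every fold's test set — and hence every
    training set — holds at least one trial per condition. Fails if any
    condition has fewer than 2 trials or if the total trial count is below
    ``N + K + 1`` (N channels after reduction, K independent variables),
    the minimum for an unbiased noise-normalized estimate.
    """
    counts = np.bincount(spec.condition_index, minlength=spec.q)
    if counts.min() < 2:
        empty = spec.unique_conditions[int(np.argmin(counts))]
        raise ValueError(
            f"condition {empty} has {counts.min()} trial(s); need at least 2"
        )
    n = len(table)
    bound = n_channels + spec.n_independent + 1
    if n < bound:
        raise ValueError(
            f"need at least N + K + 1 = {bound} trials "
            f"(N={n_channels} channels, K={spec.n_independent}), got {n}"
        )
    n_folds = int(counts.min())
    rng = np.random.default_rng(seed)
    fold_id = np.empty(n, dtype=int)
    for j in range(spec.q):
        idx = np.flatnonzero(spec.condition_index == j)
        idx = rng.permutation(idx)
        # deal round-robin from a random starting fold so remainders spread
        start = rng.integers(n_folds)
        fold_id[idx] = (start + np.arange(idx.size)) % n_folds
    return FoldAssignment(fold_id=fold_id, n_folds=n_folds, seed=seed)
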