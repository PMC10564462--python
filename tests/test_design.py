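"""Design matrix, contrasts and condition-balanced fold construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvdecode import assign_folds, build_design, simulate_subject, subset_contrast
from cvdecode.design import cell_pair_contrast
from conftest import balanced_table, cheap_params

FULL_MODEL = ("task", "stimulus", "choice", "response", "mapping",
              "accuracy", "confidence")


def test_five_independent_binaries_give_32_conditions():
    """Seven task variables with two deterministic dependencies span 32
    unique conditions and count as 5 independent variables."""
    _, table, _ = simulate_subject(cheap_params(n_trials_per_task=2000, seed=1))
    spec = build_design(table, FULL_MODEL)
    assert spec.q == 32
    assert spec.n_independent == 5


def test_rows_sum_to_one_and_contrasts_balanced():
    table = balanced_table(("task", "stimulus", "choice", "mapping"), reps=3)
    spec = build_design(table, ("task", "stimulus", "choice", "response",
                                "mapping", "accuracy"))
    assert np.allclose(spec.X.sum(axis=1), 1.0)
    for c in spec.contrasts.values():
        assert abs(c.sum()) < 1e-12
    # balanced main effects of any two variables are orthogonal
    names = list(spec.contrasts)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            assert abs(spec.contrasts[a] @ spec.contrasts[b]) < 1e-12


def test_contrast_is_difference_of_level_means():
    """Applying a contrast to condition means yields the difference of the
    two level-averaged means (scaling 1/q_half)."""
    table = balanced_table(("stimulus", "choice"), reps=4)
    spec = build_design(table, ("stimulus", "choice"))
    means = np.arange(spec.q, dtype=float)
    c = spec.contrasts["choice"]
    idx_yes = [i for i, u in enumerate(spec.unique_conditions)
               if u[spec.variables.index("choice")] == "yes"]
    idx_no = [i for i in range(spec.q) if i not in idx_yes]
    assert np.isclose(c @ means, means[idx_yes].mean() - means[idx_no].mean())


def test_deterministic_dependency_violation_rejected():
    table = balanced_table(("stimulus", "choice", "mapping"), reps=2)
    table.loc[0, "response"] = "right" if table.loc[0, "response"] == "left" \
        else "left"
    with pytest.raises(ValueError, match="response inconsistent"):
        build_design(table, ("stimulus", "choice", "response", "mapping"))


def test_constant_variable_rejected():
    table = balanced_table(("stimulus", "choice"), reps=2)
    table["task"] = "pre"
    with pytest.raises(ValueError, match="task"):
        build_design(table, ("task", "stimulus", "choice"))


def test_subset_contrast_restricted_and_rebalanced():
    table = balanced_table(("task", "stimulus", "choice", "mapping"), reps=2)
    spec = build_design(table, ("task", "stimulus", "choice", "mapping"))
    c = subset_contrast(spec, "choice", {"task": "pre"})
    outside = ~spec.condition_mask({"task": "pre"})
    assert np.all(c[outside] == 0)
    assert abs(c.sum()) < 1e-12
    with pytest.raises(ValueError, match="empties"):
        subset_contrast(spec, "task", {"task": "pre"})


def test_cell_pair_contrast():
    table = balanced_table(("stimulus", "choice"), reps=2)
    spec = build_design(table, ("stimulus", "choice", "accuracy"))
    c = cell_pair_contrast(
        spec, {"choice": "yes", "accuracy": "correct"},
        {"choice": "no", "accuracy": "correct"},
    )
    assert abs(c.sum()) < 1e-12
    with pytest.raises(ValueError, match="overlap"):
        cell_pair_contrast(spec, {"choice": "yes"}, {"accuracy": "correct"})


def test_forced_partition_five_trials_per_condition():
    """32 conditions × exactly 5 trials → 5 folds, one trial per condition
    in every test fold."""
    table = balanced_table(("task", "stimulus", "choice", "mapping",
                            "confidence"), reps=5)
    spec = build_design(table, ("task", "stimulus", "choice", "mapping",
                                "confidence"))
    assert spec.q == 32
    folds = assign_folds(table, spec, seed=0, n_channels=4)
    assert folds.n_folds == 5
    for k in range(5):
        te = folds.test_indices(k)
        counts = np.bincount(spec.condition_index[te], minlength=spec.q)
        assert np.all(counts == 1)


def test_fold_count_is_min_condition_count():
    table = balanced_table(("stimulus", "choice"), reps=7)
    spec = build_design(table, ("stimulus", "choice"))
    folds = assign_folds(table, spec, seed=1, n_channels=3)
    assert folds.n_folds == 7


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    counts=st.lists(st.integers(min_value=2, max_value=9), min_size=4,
                    max_size=4),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_every_fold_covers_every_condition(counts, seed):
    """Brute-force check: arbitrary condition counts, any seed — the fold
    partition covers all conditions in both train and test sets."""
    import pandas as pd

    levels = [("signal", "yes"), ("signal", "no"), ("noise", "yes"),
              ("noise", "no")]
    rows = []
    for (s, c), n in zip(levels, counts):
        rows.extend([{"stimulus": s, "choice": c, "run": "run1"}] * n)
    table = pd.DataFrame(rows)
    spec = build_design(table, ("stimulus", "choice"))
    folds = assign_folds(table, spec, seed=seed, n_channels=2)
    assert folds.n_folds == min(counts)
    fold_sizes = np.bincount(folds.fold_id, minlength=folds.n_folds)
    assert fold_sizes.sum() == len(table)  # partition
    for k in range(folds.n_folds):
        for idx in (folds.test_indices(k), folds.train_indices(k)):
            assert set(spec.condition_index[idx]) == set(range(spec.q))


def test_fold_assignment_deterministic_in_seed():
    table = balanced_table(("stimulus", "choice"), reps=6)
    spec = build_design(table, ("stimulus", "choice"))
    a = assign_folds(table, spec, seed=42, n_channels=2)
    b = assign_folds(table, spec, seed=42, n_channels=2)
    assert np.array_equal(a.fold_id, b.fold_id)


def test_trial_count_bound_enforced():
    table = balanced_table(("stimulus", "choice"), reps=3)
    spec = build_design(table, ("stimulus", "choice"))
    with pytest.raises(ValueError, match=r"N \+ K \+ 1"):
        assign_folds(table, spec, seed=0, n_channels=50)


def test_sparse_condition_rejected_by_name():
    table = balanced_table(("stimulus", "choice"), reps=2)
    table = table.drop(index=[0]).reset_index(drop=True)
    spec = build_design(table, ("stimulus", "choice"))
    with pytest.raises(ValueError, match="has 1 trial"):
        assign_folds(table, spec, seed=0, n_channels=2)
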