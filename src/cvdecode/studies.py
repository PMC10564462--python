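"""Study-level simulation workflows.

Each function here runs a complete scaled-down in-silico study — simulate
replicate subjects or datasets under a stated generator configuration, run
the decoding/inference pipeline, and summarize the property of interest
(estimator bias, confound exclusion, context transfer, test calibration,
decision-variable signatures, localization). They are the package's
self-characterization experiments: the problem sizes trade Monte-Carlo
precision against runtime and are documented per function.

All randomness flows from a single integer seed per study.
"""

from __future__ import annotations

import numpy as np

from .geometry import (
    axis_placement,
    choice_strength_by_group,
    predict_stimulus_from_sign,
    project_trials,
)
from .inference import cluster_permutation, compare_to_expected
from .manova import CrossValidatedMANOVA, Request, expected_cross
from .sdt import meta_dprime, sdt_summary
from .searchlight import (
    GROUPS,
    group_average,
    make_synthetic_geometry,
    searchlight_decode,
)
from .simulate import GeneratorParams, simulate_subject

# Short epoch shared by the scaled-down studies: −0.6…1.6 s at 20 Hz with a
# generic effect onset at 0.1 s. Full-length epochs change nothing about the
# properties probed here, only the runtime.
STUDY_TIME = np.arange(-0.6, 1.601, 0.05)
STUDY_RAMP = np.clip((STUDY_TIME - 0.1) / 0.3, 0.0, 1.0)
_PROFILES = {k: STUDY_RAMP for k in
             ("stimulus", "choice", "choice_pre", "choice_post", "response",
              "task", "mapping", "confidence")}


def _params(**kw) -> GeneratorParams:
    time = np.asarray(kw.get("time", STUDY_TIME))
    ramp = np.clip((time - 0.1) / 0.3, 0.0, 1.0)
    base = dict(
        n_trials_per_task=160,
        n_channels=6,
        time=time,
        temporal_profiles={k: ramp for k in _PROFILES},
        seed=0,
    )
    base.update(kw)
    return GeneratorParams(**base)


def _simulate_model(params, variables, baseline_time=-0.5, max_tries=5):
    """Simulate a subject and build its model, redrawing (new seed) the rare
    datasets whose behavioral sampling leaves a design condition with fewer
    than 2 trials — condition occupancy is independent of the estimator
    properties the studies measure."""
    last = None
    for attempt in range(max_tries):
        p = GeneratorParams(
            **{**params.__dict__, "seed": params.seed + 1_000_003 * attempt}
        )
        tensor, table, truth = simulate_subject(p)
        model = CrossValidatedMANOVA(
            tensor, table, variables=variables, baseline_time=baseline_time
        )
        counts = np.bincount(model.spec.condition_index, minlength=model.spec.q)
        if counts.min() >= 2:
            return model, table, truth
        last = counts.min()
    raise RuntimeError(
        f"could not draw a dataset with all conditions occupied "
        f"(min count {last} after {max_tries} tries)"
    )


def null_bias_study(
    n_datasets: int = 500,
    variables=("stimulus", "choice", "mapping"),
    seed: int = 0,
) -> dict:
    """Estimator bias under the null: no planted patterns, behavior intact.

    Simulates ``n_datasets`` small subjects (128 trials, 6 channels, 6 time
    points) and averages the distinctness estimate per variable and time
    point. Returns per-variable mean D, its Monte-Carlo standard error, and
    the largest |mean/SE| across variables and time points.
    """
    time = STUDY_TIME[:6]
    sums: dict[str, list[np.ndarray]] = {v: [] for v in variables}
    for r in range(n_datasets):
        params = _params(
            n_trials_per_task=64, patterns={}, time=time, seed=seed + 17 * r
        )
        model, _, _ = _simulate_model(params, variables, baseline_time=time[0])
        res = model.fit(n_seeds=1, seed=seed + r, smooth=False)
        for v in variables:
            sums[v].append(res[v])
    out = {}
    max_abs_z = 0.0
    for v in variables:
        arr = np.stack(sums[v])
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(n_datasets)
        out[v] = {"mean": mean, "se": se}
        max_abs_z = max(max_abs_z, float(np.max(np.abs(mean / se))))
    out["max_abs_z"] = max_abs_z
    out["n_tests"] = len(variables) * time.size
    return out


def confound_exclusion_study(n_datasets: int = 200, seed: int = 0) -> dict:
    """Choice decoding with stimulus and response patterns but no choice
    pattern, at near-threshold behavior (~74% correct).

    Because choices correlate with both stimulus and response, any leakage
    of their (strong) planted patterns into the choice estimate would bias
    it away from zero. Returns the per-time mean choice D, its SE, and the
    largest |mean/SE|.
    """
    time = np.arange(-0.3, 0.51, 0.05)  # covers the 0.1 s effect onset
    vals = []
    for r in range(n_datasets):
        params = _params(
            n_trials_per_task=80,
            patterns={"stimulus": 1.5, "response": 1.5},
            time=time,
            seed=seed + 31 * r,
        )
        model, _, _ = _simulate_model(
            params, ("stimulus", "choice", "response", "mapping"),
            baseline_time=time[0],
        )
        res = model.fit(
            [Request(name="choice", train="choice")],
            n_seeds=1, seed=seed + r, smooth=False,
        )
        vals.append(res["choice"])
    arr = np.stack(vals)
    mean = arr.mean(axis=0)
    se = arr.std(axis=0, ddof=1) / np.sqrt(n_datasets)
    return {
        "mean": mean,
        "se": se,
        "max_abs_z": float(np.max(np.abs(mean / se))),
        "n_tests": time.size,
    }


def _context_subject(angle: float, seed: int, amp: float = 1.2):
    params = _params(
        patterns={"choice_pre": amp, "choice_post": amp},
        overlap_angles={("choice_pre", "choice_post"): angle},
        dv_gain=0.0,
        seed=seed,
    )
    model, _, _ = _simulate_model(
        params, ("task", "stimulus", "choice", "mapping")
    )
    reqs = [
        Request(name="within_pre", train="choice", train_subset={"task": "pre"}),
        Request(name="within_post", train="choice", train_subset={"task": "post"}),
        Request(name="cross", train="choice", train_subset={"task": "pre"},
                test="choice", test_subset={"task": "post"}),
    ]
    res = model.fit(reqs, n_seeds=2, seed=seed, smooth=False)
    return res


def context_transfer_study(
    n_subjects: int = 100,
    n_groups: int = 10,
    group_size: int = 12,
    angle_shared: float = 0.0,
    angle_distinct: float = 90.0,
    n_perm: int = 100,
    seed: int = 0,
) -> dict:
    """Cross-context generalization of choice patterns.

    Shared case: identical choice patterns in the pre- and post-cue
    contexts; the cross-context distinctness should match the within-context
    level (ratio 1) and never fall significantly below the expected
    cross-decoding E12. Distinct case: orthogonal patterns; the empirical
    cross-decoding shows a significant deficit relative to E12.

    Simulates ``n_subjects`` for the ratio, reuses them in ``n_groups``
    disjoint group analyses for the deficit test, and one extra group for
    the orthogonal case. The ratio is computed on the effect plateau
    (0.5–1.6 s); the deficit comparison runs over the post-onset period
    (from 0 s), where representations exist in both contexts — comparing
    empirical against expected cross-decoding is only meaningful where
    there is information whose sharing can fall short.
    """
    window = (STUDY_TIME >= 0.5) & (STUDY_TIME <= 1.6)
    test_window = STUDY_TIME >= 0.0
    need = max(n_subjects, n_groups * group_size)
    within_w, cross_w = [], []
    emp, exp = [], []
    for s in range(need):
        res = _context_subject(angle_shared, seed + 101 * s)
        within = 0.5 * (res["within_pre"] + res["within_post"])
        within_w.append(within[window].mean())
        cross_w.append(res["cross"][window].mean())
        emp.append(res["cross"])
        exp.append(expected_cross(res["within_pre"], res["within_post"]))
    ratio = float(np.mean(cross_w[:n_subjects]) / np.mean(within_w[:n_subjects]))

    emp = np.stack(emp)[:, test_window]
    exp = np.stack(exp)[:, test_window]
    deficit_groups = 0
    for g in range(n_groups):
        ix = slice(g * group_size, (g + 1) * group_size)
        res = compare_to_expected(
            emp[ix], exp[ix], tail="one_neg", n_perm=n_perm, seed=seed + g
        )
        if any(c.p < 0.05 for c in res.clusters):
            deficit_groups += 1

    emp_o, exp_o = [], []
    for s in range(group_size):
        res = _context_subject(angle_distinct, seed + 7919 * (s + 1))
        emp_o.append(res["cross"])
        exp_o.append(expected_cross(res["within_pre"], res["within_post"]))
    res_o = compare_to_expected(
        np.stack(emp_o)[:, test_window], np.stack(exp_o)[:, test_window],
        tail="one_neg",
        n_perm=max(n_perm, 500), seed=seed,
    )
    p_orth = min((c.p for c in res_o.clusters), default=1.0)
    return {
        "cross_within_ratio": ratio,
        "n_subjects": n_subjects,
        "shared_deficit_rate": deficit_groups / n_groups,
        "n_groups": n_groups,
        "orthogonal_deficit_p": float(p_orth),
    }


def cluster_calibration_study(
    n_replicates: int = 500,
    n_subjects: int = 12,
    n_time: int = 30,
    n_perm: int = 500,
    seed: int = 0,
) -> dict:
    """Family-wise error of the cluster sign-permutation test on null data.

    White-noise group datasets; a replicate counts as a false positive if
    any cluster reaches p < 0.05. The FWER should sit inside the binomial
    95% interval around the nominal α = 0.05.
    """
    rng = np.random.default_rng(seed)
    fp = 0
    for r in range(n_replicates):
        data = rng.standard_normal((n_subjects, n_time))
        res = cluster_permutation(
            data, tail="one_pos", n_perm=n_perm, seed=seed + r
        )
        if any(c.p < 0.05 for c in res.clusters):
            fp += 1
    fwer = fp / n_replicates
    half = 1.96 * np.sqrt(0.05 * 0.95 / n_replicates)
    return {
        "fwer": fwer,
        "n_replicates": n_replicates,
        "binomial_ci": (0.05 - half, 0.05 + half),
    }


def dv_ordering_study(n_replicates: int = 40, seed: int = 0) -> dict:
    """Decision-variable signatures of the choice signal.

    With the choice-pattern amplitude coupled to |DV − criterion|
    (dv_gain = 2), choice information should order correct-high >
    {incorrect-high, correct-low} > incorrect-low across confidence ×
    accuracy cells, and the four choice × accuracy cells should place on
    the choice axis as correct-no < incorrect-no < incorrect-yes <
    correct-yes. Returns the fraction of replicates showing each ordering.
    """
    window = STUDY_TIME > 0.3
    ok_strength = ok_place = 0
    for r in range(n_replicates):
        params = _params(
            n_trials_per_task=300,
            patterns={"choice": 1.2},
            dv_gain=2.0,
            seed=seed + 53 * r,
        )
        model, _, _ = _simulate_model(
            params, ("stimulus", "choice", "mapping", "accuracy", "confidence")
        )
        strength = choice_strength_by_group(model, seed=seed + r)
        w = {k: v[window].mean() for k, v in strength.items()}
        ch, ci = w[("high", "correct")], w[("high", "incorrect")]
        cl, il = w[("low", "correct")], w[("low", "incorrect")]
        if ch > ci and ch > cl and ci > il and cl > il:
            ok_strength += 1
        pos = axis_placement(model, window=(0.3, 1.6), seed=seed + r)["positions"]
        if (pos[("no", "correct")] < pos[("no", "incorrect")]
                < pos[("yes", "incorrect")] < pos[("yes", "correct")]):
            ok_place += 1
    return {
        "strength_ordering_rate": ok_strength / n_replicates,
        "placement_ordering_rate": ok_place / n_replicates,
        "n_replicates": n_replicates,
    }


def stimulus_prediction_study(n_subjects: int = 8, seed: int = 0) -> dict:
    """Stimulus predictability from the sign of choice-axis projections.

    Under the SDT generator (choices right ~74% of the time), the choice
    axis predicts the stimulus above chance after the effect onset but not
    before it. Returns per-subject pre- and post-onset accuracies.
    """
    pre_mask = STUDY_TIME < 0.0
    post_mask = STUDY_TIME > 0.5
    pre, post = [], []
    for s in range(n_subjects):
        params = _params(
            n_trials_per_task=250, patterns={"choice": 1.2}, seed=seed + 211 * s
        )
        model, table, _ = _simulate_model(
            params, ("stimulus", "choice", "mapping")
        )
        proj = project_trials(model, "choice", seed=seed + s)
        acc = predict_stimulus_from_sign(proj, table)
        pre.append(acc[pre_mask].mean())
        post.append(acc[post_mask].mean())
    return {
        "pre_onset_accuracy": np.asarray(pre),
        "post_onset_accuracy": np.asarray(post),
    }


def sdt_recovery_study(n_trials: int = 10_000, seed: int = 0) -> dict:
    """Round-trip recovery of signal-detection quantities.

    d′: planted 1.35, recovered from 10,000 simulated trials. meta-d′:
    ideal type-2 behavior (confidence from the same evidence) should give
    meta-d′ ≈ d′; adding metacognitive noise to the confidence evidence
    should strictly lower it.
    """
    params = _params(
        n_trials_per_task=n_trials // 2,
        stimulus_effect=1.35, criterion=0.675,
        prior_sd=0.0, sequential_weight=0.0,
        patterns={}, n_channels=1, time=STUDY_TIME[:3],
        seed=seed,
    )
    _, table, _ = simulate_subject(params)
    s = sdt_summary(table)
    ideal = meta_dprime(s.confidence_counts)

    rng = np.random.default_rng(seed + 1)
    metas = []
    for t2_sd in (0.0, 0.75, 1.5):
        stim = rng.random(4 * n_trials) < 0.5
        x = np.where(stim, 1.35 / 2, -1.35 / 2) + rng.standard_normal(4 * n_trials)
        yes = x > 0.0
        x2 = x + t2_sd * rng.standard_normal(4 * n_trials)
        high = np.abs(x2) > 0.7
        counts = np.zeros((2, 2, 2))
        for i, sv in enumerate((True, False)):
            for j, cv in enumerate((True, False)):
                for k, hv in enumerate((True, False)):
                    counts[i, j, k] = np.sum(
                        (stim == sv) & (yes == cv) & (high == hv)
                    )
        metas.append(meta_dprime(counts).meta_dprime)
    return {
        "dprime_planted": 1.35,
        "dprime_recovered": s.dprime,
        "meta_dprime_ideal": ideal.meta_dprime,
        "meta_dprime_vs_t2_noise": metas,
        "n_trials": n_trials,
    }


def searchlight_localization_study(
    n_replicates: int = 12,
    n_sources: int = 24,
    target_group: str = "occipital",
    seed: int = 0,
) -> dict:
    """Localization of a single-region planted effect.

    A choice pattern confined to one region's channels should make that
    region's group-averaged, √size-normalized information the largest of
    the four groups. Returns the fraction of replicates where it is.
    """
    geometry = make_synthetic_geometry(n_sources=n_sources)
    n_channels = geometry.n_sources * geometry.n_dipole
    members = np.flatnonzero(geometry.group_labels == target_group)
    v = np.zeros(n_channels)
    for s in members:
        v[3 * s: 3 * s + 3] = 1.0
    v /= np.linalg.norm(v)
    time = STUDY_TIME[:25]
    window = time > 0.3
    hits = 0
    for r in range(n_replicates):
        params = _params(
            n_trials_per_task=150,
            n_channels=n_channels,
            time=time,
            patterns={"choice": 1.5},
            pattern_bank={"choice": v},
            dv_gain=0.0,
            seed=seed + 307 * r,
        )
        model, table, _ = _simulate_model(
            params, ("stimulus", "choice"), baseline_time=time[0]
        )
        tensor = model.tensor
        info = searchlight_decode(
            tensor, table, geometry, ("stimulus", "choice"),
            variable="choice", seed=seed + r, baseline_time=time[0],
        )
        groups = group_average(info, geometry)
        means = {g: groups[g][window].mean() for g in GROUPS}
        if max(means, key=means.get) == target_group:
            hits += 1
    return {
        "localization_rate": hits / n_replicates,
        "n_replicates": n_replicates,
        "target_group": target_group,
    }
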