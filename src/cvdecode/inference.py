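"""Group-level statistics: cluster-based sign-permutation tests on time
courses and time × time generalization matrices, window-averaged t-tests,
and the empirical-vs-expected cross-decoding comparison.

The permutation scheme exploits the null symmetry of a zero-mean effect:
each subject's whole statistic array is multiplied by ±1, the one-sample
t-map recomputed, supra-threshold clusters re-formed, and the maximal
cluster mass recorded. Cluster mass is the sum of t-values within a
cluster; contiguity is temporal adjacency in 1D and 4-neighborhood on the
time × time grid. The observed clusters' p-values carry the +1 finite-
sample correction, so their resolution is 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.stats

__all__ = [
    "Cluster",
    "ClusterResult",
    "cluster_permutation",
    "compare_to_expected",
    "ttest_window",
]


@dataclass
class Cluster:
    """One supra-threshold cluster: member indices, mass and p-value."""

    indices: np.ndarray
    mass: float
    p: float

    def bounds(self, time: np.ndarray) -> tuple[float, float]:
        """Cluster extent in seconds along the (first) time axis."""
        first = np.atleast_2d(self.indices)[:, 0] if self.indices.ndim > 1 \
            else self.indices
        return float(time[first.min()]), float(time[first.max()])


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    tail: str
    n_perm: int
    alpha_forming: float
    t_obs: np.ndarray
    null_max_mass: np.ndarray = field(repr=False)

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p < 0.05]

    def to_json_dict(self, time: np.ndarray | None = None) -> dict:
        out = []
        for c in self.clusters:
            entry = {"mass": c.mass, "p": c.p, "size": int(len(c.indices))}
            if time is not None:
                entry["bounds_s"] = list(c.bounds(time))
            out.append(entry)
        return {"tail": self.tail, "n_perm": self.n_perm, "clusters": out}


def _tvalues(data: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0, zero where the spread vanishes with the mean."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)


def _clusters_and_masses(t: np.ndarray, thresh: float, sign: int):
    """Clusters of ``sign·t > thresh`` with signed masses (sum of t)."""
    mask = (sign * t) > thresh
    if t.ndim == 1:
        labels, n = scipy.ndimage.label(mask)
    else:
        labels, n = scipy.ndimage.label(mask)  # default structure = 4-neighborhood
    out = []
    for lab in range(1, n + 1):
        idx = np.argwhere(labels == lab)
        if t.ndim == 1:
            idx = idx[:, 0]
        out.append((idx, float(t[labels == lab].sum())))
    return out


def _max_abs_mass(t: np.ndarray, thresh: float, tails: tuple[int, ...]) -> float:
    best = 0.0
    for sign in tails:
        for _, mass in _clusters_and_masses(t, thresh, sign):
            best = max(best, abs(mass))
    return best


def cluster_permutation(
    data: np.ndarray,
    tail: str = "one_pos",
    alpha_forming: float = 0.05,
    n_perm: int = 10000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based sign-permutation test of a zero-mean null.

    Parameters
    ----------
    data
        Per-subject statistic, shape (n_subjects, T) or (n_subjects, T, T).
    tail
        ``one_pos``, ``one_neg`` or ``two``. Cluster-forming thresholds the
        per-point t at ``alpha_forming`` for the requested tail(s).
    n_perm
        Number of random ±1 sign assignments.

    Returns a :class:`ClusterResult`; each observed cluster's p-value is
    ``(1 + #{permutation max mass ≥ observed}) / (1 + n_perm)``, comparing
    absolute masses against the permutation distribution of the maximal
    cluster mass (FWER-controlling by construction).
    """
    data = np.asarray(data, dtype=float)
    n_subj = data.shape[0]
    if n_subj < 2:
        raise ValueError("cluster permutation needs at least 2 subjects")
    if tail not in ("one_pos", "one_neg", "two"):
        raise ValueError(f"unknown tail {tail!r}")
    df = n_subj - 1
    if tail == "two":
        thresh = scipy.stats.t.ppf(1 - alpha_forming / 2, df)
        tails: tuple[int, ...] = (1, -1)
    else:
        thresh = scipy.stats.t.ppf(1 - alpha_forming, df)
        tails = (1,) if tail == "one_pos" else (-1,)

    t_obs = _tvalues(data)
    observed: list[tuple[np.ndarray, float]] = []
    for sign in tails:
        observed.extend(_clusters_and_masses(t_obs, thresh, sign))

    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    flat = data.reshape(n_subj, -1)
    ss = np.sum(flat**2, axis=0)
    null_max = np.empty(n_perm)
    shape = data.shape[1:]
    for i in range(n_perm):
        m = flips[i] @ flat
        mean = m / n_subj
        var = (ss - n_subj * mean**2) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n_subj)
        t = np.nan_to_num(t, nan=0.0).reshape(shape)
        null_max[i] = _max_abs_mass(t, thresh, tails)

    clusters = [
        Cluster(
            indices=idx,
            mass=mass,
            p=float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm)),
        )
        for idx, mass in observed
    ]
    clusters.sort(key=lambda c: c.p)
    return ClusterResult(
        clusters=clusters,
        tail=tail,
        n_perm=n_perm,
        alpha_forming=alpha_forming,
        t_obs=t_obs,
        null_max_mass=null_max,
    )


def compare_to_expected(
    empirical: np.ndarray,
    expected: np.ndarray,
    tail: str = "one_neg",
    **kw,
) -> ClusterResult:
    """Test whether empirical cross-decoding falls short of the expected
    cross-decoding: a cluster sign-permutation test on the per-subject
    difference (empirical − expected), one-tailed for deficits by default.
    A significant (negative) cluster indicates representations that are not
    fully shared between the two contexts.
    """
    empirical = np.asarray(empirical, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if empirical.shape != expected.shape:
        raise ValueError("empirical and expected arrays must share shape")
    return cluster_permutation(empirical - expected, tail=tail, **kw)


def ttest_window(
    data: np.ndarray,
    time: np.ndarray,
    window: tuple[float, float],
    tail: str = "one_pos",
) -> tuple[float, float]:
    """Across-subject t-test of the window-averaged statistic.

    Averages each subject's time course over ``window`` (seconds, inclusive)
    and returns (t, p) for the requested tail.
    """
    lo, hi = window
    mask = (np.asarray(time) >= lo) & (np.asarray(time) <= hi)
    if not mask.any():
        raise ValueError(f"window {window} contains no time samples")
    means = np.asarray(data, dtype=float)[:, mask].mean(axis=1)
    t, p = scipy.stats.ttest_1samp(means, 0.0)
    if tail == "one_pos":
        p = p / 2 if t > 0 else 1 - p / 2
    elif tail == "one_neg":
        p = p / 2 if t < 0 else 1 - p / 2
    elif tail != "two":
        raise ValueError(f"unknown tail {tail!r}")
    return float(t), float(p)
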