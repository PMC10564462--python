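"""Derived readouts of the fitted decoding model: single-trial projections
onto the choice axis, stimulus prediction from their sign, placement of
choice × accuracy cells on the choice axis, and low-dimensional geometry
reconstruction from decoding values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import LEVELS
from .design import cell_pair_contrast, subset_contrast
from .manova import CrossValidatedMANOVA, Request

__all__ = [
    "project_trials",
    "predict_stimulus_from_sign",
    "choice_strength_by_group",
    "axis_placement",
    "GeometryLayout",
    "reconstruct_geometry",
]


def project_trials(
    model: CrossValidatedMANOVA,
    axis_variable: str = "choice",
    axis_subset: dict[str, str] | None = None,
    n_seeds: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold projection of every trial onto a decoding axis.

    Per fold, the axis is the noise-whitened contrast of training betas,
    ``a(t) = Σ⁻¹ (C' B_train(t))'``; each *test* trial's data at each time
    point is projected onto it, so no trial's projection ever uses its own
    fold's training data. Positive values lie on the positive-level side of
    the training contrast (``yes`` for the choice axis). Returns an array
    (n_trials, n_time), averaged over ``n_seeds`` fold partitions.
    """
    c = subset_contrast(model.spec, axis_variable, axis_subset)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(2**31 - 1, size=n_seeds)
    out = np.zeros((model.tensor.n_trials, model.tensor.n_time))
    hits = np.zeros(model.tensor.n_trials)
    for fs_ in fold_seeds:
        for tr, te, B_tr, B_te, P, counts in model.fold_fits(int(fs_)):
            delta = np.einsum("q,qpt->pt", c, B_tr)
            axis = P @ delta                     # (p, T), whitened contrast
            if not np.any(axis):
                raise ValueError("projection axis has zero length")
            out[te] += np.einsum("ipt,pt->it", model.tensor.data[te], axis)
            hits[te] += 1.0
    return out / hits[:, None]


def predict_stimulus_from_sign(projections: np.ndarray, table) -> np.ndarray:
    """Fraction of trials whose projection sign matches the stimulus class.

    Returns a per-time accuracy in [0, 1]; chance is 0.5. Under a
    signal-detection generator the choice axis carries stimulus information
    only insofar as choices covary with the stimulus, so predictability
    should rise after stimulus onset and sit at chance before it.
    """
    truth = (table["stimulus"].to_numpy() == LEVELS["stimulus"][0])
    signs = projections > 0
    return (signs == truth[:, None]).mean(axis=0)


def choice_strength_by_group(
    model: CrossValidatedMANOVA,
    n_seeds: int = 1,
    seed: int = 0,
    smooth: bool = False,
) -> dict[tuple[str, str], np.ndarray]:
    """Choice distinctness per (confidence, accuracy) cell over time.

    Trains the choice contrast separately on high- and low-confidence trials
    and tests it on the matching confidence × accuracy subset, yielding the
    four time courses whose ordering (correct-high strongest, incorrect-low
    weakest) is the decision-variable signature.
    """
    requests = []
    for conf in LEVELS["confidence"]:
        for acc in LEVELS["accuracy"]:
            requests.append(
                Request(
                    name=f"{conf}_{acc}",
                    train="choice",
                    train_subset={"confidence": conf},
                    test="choice",
                    test_subset={"confidence": conf, "accuracy": acc},
                    symmetric=False,
                )
            )
    res = model.fit(requests, n_seeds=n_seeds, seed=seed, smooth=smooth)
    return {
        (conf, acc): res[f"{conf}_{acc}"]
        for conf in LEVELS["confidence"]
        for acc in LEVELS["accuracy"]
    }


_CELLS = (
    ("yes", "correct"),
    ("no", "correct"),
    ("yes", "incorrect"),
    ("no", "incorrect"),
)


def axis_placement(
    model: CrossValidatedMANOVA,
    window: tuple[float, float] = (1.25, 4.0),
    n_seeds: int = 1,
    seed: int = 0,
) -> dict:
    """Placement of the four choice × accuracy cells on the choice axis.

    A decoding model trained on *all* choices is tested on three cell
    pairs — correct-yes vs correct-no, incorrect-yes vs incorrect-no, and
    correct-yes vs incorrect-no. Signed distances ``sign(D)·√|D|`` between
    those pairs (window-averaged) are embedded on a line by least squares
    and normalized so correct-no sits at −1 and correct-yes at +1. Under a
    decision-variable account the cells order correct-no < incorrect-no <
    incorrect-yes < correct-yes.
    """
    pairs = [
        (("yes", "correct"), ("no", "correct")),
        (("yes", "incorrect"), ("no", "incorrect")),
        (("yes", "correct"), ("no", "incorrect")),
    ]
    requests = []
    for k, (a, b) in enumerate(pairs):
        c_test = cell_pair_contrast(
            model.spec,
            {"choice": a[0], "accuracy": a[1]},
            {"choice": b[0], "accuracy": b[1]},
        )
        requests.append(
            Request(name=f"pair{k}", train="choice", test=c_test, symmetric=False)
        )
    res = model.fit(requests, n_seeds=n_seeds, seed=seed, smooth=False)
    d = np.array(
        [res.window_mean(f"pair{k}", window) for k in range(len(pairs))]
    )
    dist = np.sign(d) * np.sqrt(np.abs(d))
    positions, residual = embed_line(dict(zip(pairs, dist)))
    return {
        "positions": positions,
        "distances": dict(zip(["cy_cn", "iy_in", "cy_in"], dist.tolist())),
        "embedding_residual": residual,
    }


def embed_line(
    pair_distances: dict[tuple[tuple[str, str], tuple[str, str]], float],
) -> tuple[dict[tuple[str, str], float], float]:
    """Least-squares 1D embedding of the four choice × accuracy cells.

    ``pair_distances`` maps (cell_a, cell_b) to the signed distance
    ``x_a − x_b``; positions are solved with a zero-sum gauge and normalized
    so correct-no = −1 and correct-yes = +1. If those anchors coincide the
    normalization is degenerate: a warning is issued and all positions are
    returned as 0. Returns (positions, sum of squared embedding residuals).
    """
    cell_ix = {c: k for k, c in enumerate(_CELLS)}
    pairs = list(pair_distances)
    A = np.zeros((len(pairs) + 1, 4))
    rhs = np.zeros(len(pairs) + 1)
    for k, (a, b) in enumerate(pairs):
        A[k, cell_ix[a]] = 1.0
        A[k, cell_ix[b]] = -1.0
        rhs[k] = pair_distances[(a, b)]
    A[-1, :] = 1.0
    x, *_ = np.linalg.lstsq(A, rhs, rcond=None)

    x_cy, x_cn = x[cell_ix[("yes", "correct")]], x[cell_ix[("no", "correct")]]
    span = x_cy - x_cn
    if abs(span) < 1e-12:
        warnings.warn(
            "degenerate normalization: correct-yes and correct-no coincide "
            "on the choice axis; returning unnormalized zeros"
        )
        positions = {c: 0.0 for c in _CELLS}
    else:
        centre = 0.5 * (x_cy + x_cn)
        positions = {c: float(2 * (x[cell_ix[c]] - centre) / span) for c in _CELLS}
    residual = float(np.sum((A[:-1] @ x - rhs[:-1]) ** 2))
    return positions, residual


@dataclass
class GeometryLayout:
    """2D layout of condition-difference vectors.

    Vector lengths are √D (distinctness units); the angle between two
    vectors satisfies cos θ = D_cross / √(D1·D2). The first vector lies on
    the horizontal axis; further vectors are placed by their angle to it
    (positive-y half-plane), so only angles to the first vector are exactly
    preserved when more than two vectors are laid out.
    """

    names: list[str]
    coords: np.ndarray          # (n, 2)
    lengths: np.ndarray         # (n,)

    def angle(self, a: str, b: str) -> float:
        """Angle (degrees) between two laid-out vectors."""
        va = self.coords[self.names.index(a)]
        vb = self.coords[self.names.index(b)]
        cos = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def implied_cross(self, a: str, b: str) -> float:
        """Cross-decoding value regenerated from the layout."""
        va = self.coords[self.names.index(a)]
        vb = self.coords[self.names.index(b)]
        return float(va @ vb)

    def implied_within(self, a: str) -> float:
        return float(self.lengths[self.names.index(a)] ** 2)


def reconstruct_geometry(
    D_within: dict[str, float],
    D_cross: dict[tuple[str, str], float],
) -> GeometryLayout:
    """Lay out condition-difference vectors from decoding values.

    Each variable's vector has length √D; the angle between two variables'
    vectors is arccos(D_cross / √(D1·D2)), with the cosine clipped to
    [−1, 1]. Fails if any within-variable D is nonpositive, since the
    corresponding angle is undefined.
    """
    bad = [k for k, v in D_within.items() if v <= 0]
    if bad:
        raise ValueError(
            f"nonpositive within-variable distinctness for {bad}; "
            "angles are undefined"
        )
    names = list(D_within)
    lengths = np.sqrt(np.array([D_within[k] for k in names]))
    coords = np.zeros((len(names), 2))
    coords[0] = [lengths[0], 0.0]
    for k, name in enumerate(names[1:], start=1):
        pair = (names[0], name) if (names[0], name) in D_cross else (name, names[0])
        if pair not in D_cross:
            raise ValueError(f"missing cross-decoding value for {names[0]}–{name}")
        cos = D_cross[pair] / (lengths[0] * lengths[k])
        theta = np.arccos(np.clip(cos, -1.0, 1.0))
        coords[k] = lengths[k] * np.array([np.cos(theta), np.sin(theta)])
    return GeometryLayout(names=names, coords=coords, lengths=lengths)
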