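"""Spatially resolved decoding over source neighborhoods.

Each source contributes a searchlight consisting of itself and its immediate
neighbors, with all three dipole directions per source, so a neighborhood of
``m`` sources spans ``3m`` data channels. Distinctness values are divided by
the square root of the searchlight's channel count to keep differently sized
neighborhoods comparable. Sources carry one of four region labels
(occipital, temporal, central, frontal) and a hemisphere label; group time
courses average homologous sources across hemispheres first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TrialTensor
from .manova import CrossValidatedMANOVA, Request

__all__ = [
    "SourceGeometry",
    "make_synthetic_geometry",
    "searchlight_decode",
    "group_average",
    "spatial_correlation",
]

GROUPS = ("occipital", "temporal", "central", "frontal")


@dataclass
class SourceGeometry:
    """Source positions, searchlight neighborhoods and region labels."""

    positions: np.ndarray               # (S, 3) in mm
    neighborhoods: list[np.ndarray]     # per-source source-index sets
    group_labels: np.ndarray            # (S,) in GROUPS
    hemisphere: np.ndarray              # (S,) 'left'/'right'
    mirror_partner: np.ndarray          # (S,) index of homologous source
    n_dipole: int = 3

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]

    def __post_init__(self) -> None:
        for s, nb in enumerate(self.neighborhoods):
            if s not in nb:
                raise ValueError(f"source {s} missing from its own neighborhood")
        if set(np.unique(self.group_labels)) - set(GROUPS):
            raise ValueError("unknown region label")

    def channel_indices(self, source: int) -> np.ndarray:
        """Data-channel indices of the searchlight centred on ``source``."""
        members = np.asarray(self.neighborhoods[source])
        return (members[:, None] * self.n_dipole + np.arange(self.n_dipole)).ravel()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "positions": self.positions.tolist(),
            "neighborhoods": [nb.tolist() for nb in self.neighborhoods],
            "group_labels": self.group_labels.tolist(),
            "hemisphere": self.hemisphere.tolist(),
            "mirror_partner": self.mirror_partner.tolist(),
            "n_dipole": self.n_dipole,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "SourceGeometry":
        d = json.loads(Path(path).read_text())
        return cls(
            positions=np.asarray(d["positions"], float),
            neighborhoods=[np.asarray(nb, int) for nb in d["neighborhoods"]],
            group_labels=np.asarray(d["group_labels"]),
            hemisphere=np.asarray(d["hemisphere"]),
            mirror_partner=np.asarray(d["mirror_partner"], int),
            n_dipole=int(d["n_dipole"]),
        )


def make_synthetic_geometry(
    n_sources: int = 457,
    radius_mm: float = 80.0,
    neighbor_factor: float = 1.5,
    n_dipole: int = 3,
) -> SourceGeometry:
    """Deterministic sphere-like source lattice with region labels.

    Sources sit on a Fibonacci lattice over the sphere (approximately
    equally spaced); neighborhoods contain all sources within 1.5 median
    nearest-neighbor spacings. Region labels partition the lattice into
    four bands along the anterior–posterior (y) axis — a synthetic stand-in
    for an anatomical parcellation that preserves the grouping and
    adjacency structure the analysis needs. Hemispheres split at x = 0 and
    homologous sources are mirror-matched.
    """
    i = np.arange(n_sources)
    golden = (1 + np.sqrt(5)) / 2
    z = 1 - 2 * (i + 0.5) / n_sources
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    pos = radius_mm * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])

    d2 = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d2, np.inf)
    spacing = float(np.median(d2.min(axis=1)))
    neighborhoods = []
    for s in i:
        dist = d2[s].copy()
        dist[s] = 0.0
        neighborhoods.append(np.flatnonzero(dist <= neighbor_factor * spacing))

    y = pos[:, 1]
    edges = np.quantile(y, [0.25, 0.5, 0.75])
    group_labels = np.empty(n_sources, dtype=object)
    group_labels[y <= edges[0]] = "occipital"
    group_labels[(y > edges[0]) & (y <= edges[1])] = "temporal"
    group_labels[(y > edges[1]) & (y <= edges[2])] = "central"
    group_labels[y > edges[2]] = "frontal"

    hemisphere = np.where(pos[:, 0] < 0, "left", "right")
    mirrored = pos * np.array([-1.0, 1.0, 1.0])
    mirror_partner = np.array([
        int(np.argmin(np.linalg.norm(pos - m, axis=1))) for m in mirrored
    ])
    return SourceGeometry(
        positions=pos,
        neighborhoods=neighborhoods,
        group_labels=group_labels.astype(str),
        hemisphere=hemisphere,
        mirror_partner=mirror_partner,
        n_dipole=n_dipole,
    )


def searchlight_decode(
    tensor: TrialTensor,
    table: pd.DataFrame,
    geometry: SourceGeometry,
    variables,
    variable: str = "choice",
    subset: dict[str, str] | None = None,
    n_seeds: int = 1,
    seed: int = 0,
    reg: float = 0.05,
    baseline_time: float = -0.5,
    smooth: bool = False,
) -> np.ndarray:
    """Per-source normalized information map, shape (S, T).

    Runs the cross-validated MANOVA within each searchlight and divides the
    resulting distinctness by √(channel count of the neighborhood). Fails
    naming the source if a neighborhood is too large for the available
    trials (the noise estimate needs ``fE > p + 1``).
    """
    if tensor.n_channels != geometry.n_sources * geometry.n_dipole:
        raise ValueError(
            f"tensor has {tensor.n_channels} channels; geometry implies "
            f"{geometry.n_sources * geometry.n_dipole}"
        )
    maps = np.empty((geometry.n_sources, tensor.n_time))
    request = [Request(name=variable, train=variable, train_subset=subset)]
    for s in range(geometry.n_sources):
        ch = geometry.channel_indices(s)
        sub = tensor.copy_with(tensor.data[:, ch, :], channel_pos=None)
        model = CrossValidatedMANOVA(
            sub, table, variables=variables, reg=reg, baseline_time=baseline_time
        )
        try:
            res = model.fit(request, n_seeds=n_seeds, seed=seed, smooth=smooth)
        except ValueError as err:
            raise ValueError(
                f"searchlight at source {s} ({ch.size} channels) failed: {err}"
            ) from err
        maps[s] = res[variable] / np.sqrt(ch.size)
    return maps


def hemisphere_average(info_map: np.ndarray, geometry: SourceGeometry) -> np.ndarray:
    """Average each source with its mirror-homologous partner."""
    return 0.5 * (info_map + info_map[geometry.mirror_partner])


def group_average(
    info_map: np.ndarray,
    geometry: SourceGeometry,
    average_hemispheres: bool = True,
) -> dict[str, np.ndarray]:
    """Mean normalized information per region group over time.

    Homologous sources are averaged across hemispheres first; fails if any
    region group contains no sources.
    """
    m = hemisphere_average(info_map, geometry) if average_hemispheres else info_map
    out = {}
    for g in GROUPS:
        idx = np.flatnonzero(geometry.group_labels == g)
        if idx.size == 0:
            raise ValueError(f"region group {g!r} is empty")
        out[g] = m[idx].mean(axis=0)
    return out


def spatial_correlation(
    info_map: np.ndarray,
    reference_map: np.ndarray,
    time: np.ndarray | None = None,
    reference_window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Correlate the cortical information distribution with a reference.

    ``reference_map`` is (S,) or (S, T); in the latter case it is averaged
    over ``reference_window`` (seconds) first. Returns the Pearson
    correlation across sources at each time point — e.g. the choice map
    against the stimulus map during stimulus presentation, to track a shift
    of choice information from sensory to motor distributions.
    """
    ref = np.asarray(reference_map, dtype=float)
    if ref.ndim == 2:
        if reference_window is None or time is None:
            raise ValueError("time and reference_window needed for a 2D reference")
        lo, hi = reference_window
        mask = (time >= lo) & (time <= hi)
        if not mask.any():
            raise ValueError("reference window contains no samples")
        ref = ref[:, mask].mean(axis=1)
    if np.std(ref) == 0:
        raise ValueError("reference map has zero variance across sources")
    m = np.asarray(info_map, dtype=float)
    sd = m.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("information map has zero variance at some time point")
    mz = (m - m.mean(axis=0)) / sd
    rz = (ref - ref.mean()) / ref.std()
    return mz.T @ rz / m.shape[0]
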