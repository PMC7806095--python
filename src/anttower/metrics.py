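"""Tower geometry: height maps, labeling, per-tower summaries, steady state.

A tower is an 8-connected component of the nonzero pixels of the
locked-stack height map, merged across the periodic boundary.  Every
agent (free agents included) is assigned the label of the pixel it
stands on; the properties reported for a run are those of the tower
holding the most agents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import periodic_centroid
from .world import WorldState

__all__ = [
    "TowerSummary",
    "height_map",
    "label_towers",
    "tower_summaries",
    "largest_tower",
    "steady_state",
]

_STRUCTURE_8 = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class TowerSummary:
    """Geometric summary of one labeled tower.

    ``n_agents`` counts every agent on the tower's footprint, free
    agents standing on it included; ``height`` is the maximum stack
    height over the footprint; ``eq_diameter = 2 * sqrt(base_area / pi)``
    is the diameter of the circle with the footprint's area; the aspect
    ratio is ``height / eq_diameter``; ``center`` is the periodic
    centroid of the footprint pixels.
    """

    label: int
    n_agents: int
    height: int
    base_area: int
    eq_diameter: float
    aspect_ratio: float
    center: tuple

    @staticmethod
    def empty() -> "TowerSummary":
        """Sentinel for a world with no towers at all."""
        return TowerSummary(0, 0, 0, 0, 0.0, 0.0, (np.nan, np.nan))


def height_map(world: WorldState) -> np.ndarray:
    """The 2D locked-stack height field; free agents contribute nothing."""
    return world.height.copy()


def label_towers(hm: np.ndarray) -> np.ndarray:
    """8-connected components of the nonzero height-map support.

    Components touching across the periodic boundary (edge or corner)
    are merged, consistent with periodic distances everywhere else in
    the model.  Zero pixels get label 0; tower labels are dense from 1,
    ordered by the first-labeled pixel of scipy's raster scan.
    """
    hm = np.asarray(hm)
    labels, n = ndimage.label(hm > 0, structure=_STRUCTURE_8)
    if n == 0:
        return labels
    # union-find over seam adjacencies
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    Lx, Ly = labels.shape
    for y in range(Ly):
        a = labels[Lx - 1, y]
        if a:
            for dy in (-1, 0, 1):
                b = labels[0, (y + dy) % Ly]
                if b:
                    union(a, b)
    for x in range(Lx):
        a = labels[x, Ly - 1]
        if a:
            for dx in (-1, 0, 1):
                b = labels[(x + dx) % Lx, 0]
                if b:
                    union(a, b)

    roots = np.array([find(k) for k in range(n + 1)])
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, uniq.size + 1)
    return remap[roots[labels]]


def tower_summaries(world: WorldState, labels: np.ndarray | None = None) -> list:
    """One :class:`TowerSummary` per labeled tower of ``world``.

    ``labels`` defaults to ``label_towers(height_map(world))`` and must
    share the world's grid if supplied.
    """
    if labels is None:
        labels = label_towers(height_map(world))
    n_labels = int(labels.max())
    out = []
    if n_labels == 0:
        return out
    free_ids = np.flatnonzero(~world.locked)
    free_label_counts = np.bincount(
        labels[world.agent_x[free_ids], world.agent_y[free_ids]],
        minlength=n_labels + 1,
    )
    for lab in range(1, n_labels + 1):
        mask = labels == lab
        base_area = int(mask.sum())
        stacked = int(world.height[mask].sum())
        n_agents = stacked + int(free_label_counts[lab])
        h = int(world.height[mask].max())
        eq_d = 2.0 * np.sqrt(base_area / np.pi)
        xs, ys = np.nonzero(mask)
        center = periodic_centroid(np.column_stack([xs, ys]), world.L)
        out.append(
            TowerSummary(
                label=lab,
                n_agents=n_agents,
                height=h,
                base_area=base_area,
                eq_diameter=eq_d,
                aspect_ratio=h / eq_d,
                center=(float(center[0]), float(center[1])),
            )
        )
    return out


def largest_tower(summaries: list) -> TowerSummary:
    """The tower with the most agents (ties: lowest label; empty: sentinel)."""
    if not summaries:
        return TowerSummary.empty()
    best = summaries[0]
    for s in summaries[1:]:
        if s.n_agents > best.n_agents or (
            s.n_agents == best.n_agents and s.label < best.label
        ):
            best = s
    return best


def steady_state(
    times: np.ndarray,
    largest_sizes: np.ndarray,
    N: int,
    window: int = 100_000,
) -> bool:
    """Has the largest-tower size settled to within ``+-5%`` of ``N``?

    True iff the series spans at least ``window`` steps and over the
    trailing ``window`` the largest-tower size varies (max minus min) by
    no more than ``0.05 * N``.
    """
    times = np.asarray(times)
    sizes = np.asarray(largest_sizes)
    if times.size == 0:
        raise ValueError("empty time series")
    if times.size != sizes.size:
        raise ValueError("times and sizes must have equal length")
    span = times[-1] - times[0]
    if span < window:
        return False
    tail = sizes[times >= times[-1] - window]
    return float(tail.max() - tail.min()) <= 0.05 * N
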