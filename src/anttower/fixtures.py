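"""Deterministic miniature worlds used across the test suite and docs."""

from __future__ import annotations

import numpy as np

from .world import WorldState

__all__ = ["world_from_height_map", "make_fixture", "FIXTURE_NAMES"]


def world_from_height_map(hm: np.ndarray, free_pixels=()) -> WorldState:
    """Build a consistent world from a locked-stack height map.

    Locked agents are created bottom-up at each nonzero pixel (ids in
    raster order), then one free agent per entry of ``free_pixels`` is
    placed on the surface of its pixel.
    """
    hm = np.asarray(hm, dtype=np.int64)
    if hm.ndim != 2 or hm.shape[0] != hm.shape[1]:
        raise ValueError("height map must be a square 2D array")
    L = hm.shape[0]
    xs, ys, zs, lock = [], [], [], []
    for x in range(L):
        for y in range(L):
            for z in range(hm[x, y]):
                xs.append(x)
                ys.append(y)
                zs.append(z)
                lock.append(True)
    free_occ = np.full((L, L), -1, dtype=np.int64)
    for px, py in free_pixels:
        if free_occ[px, py] >= 0:
            raise ValueError(f"two free agents requested at pixel {(px, py)}")
        free_occ[px, py] = len(xs)
        xs.append(px)
        ys.append(py)
        zs.append(int(hm[px, py]))
        lock.append(False)
    return WorldState(
        L=L,
        height=hm.copy(),
        free_occ=free_occ,
        agent_x=np.array(xs, dtype=np.int64),
        agent_y=np.array(ys, dtype=np.int64),
        agent_z=np.array(zs, dtype=np.int64),
        locked=np.array(lock, dtype=bool),
        t=0,
    )


def _empty_flat():
    return WorldState.empty(10)


def _single_stack_4():
    hm = np.zeros((9, 9), dtype=np.int64)
    hm[3, 3] = 4
    return world_from_height_map(hm)


def _seam_tower():
    # a 2x2 tower straddling the x periodic boundary
    hm = np.zeros((10, 10), dtype=np.int64)
    for x in (9, 0):
        for y in (4, 5):
            hm[x, y] = 2
    return world_from_height_map(hm)


def _two_towers_merge():
    """Frame sequence (list of height maps) of two towers merging.

    A stationary 3x3 tower and a second one walking one pixel left per
    frame; in the last frame they touch and label as one component.
    """
    frames = []
    L = 16
    for x0 in (9, 8, 7, 6):  # contact (8-adjacency) at x0 = 6
        hm = np.zeros((L, L), dtype=np.int64)
        hm[3:6, 7:10] = 3
        hm[x0 : x0 + 3, 7:10] = 2
        frames.append(hm)
    return frames


def _dla_seed():
    hm = np.zeros((21, 21), dtype=np.int64)
    hm[10, 10] = 1
    return world_from_height_map(hm)


_REGISTRY = {
    "empty-flat": _empty_flat,
    "single-stack-4": _single_stack_4,
    "seam-tower": _seam_tower,
    "two-towers-merge": _two_towers_merge,
    "dla-seed": _dla_seed,
}

FIXTURE_NAMES = tuple(_REGISTRY)


def make_fixture(name: str):
    """Return a named deterministic fixture world (or frame sequence)."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
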