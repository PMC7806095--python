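"""Periodic-lattice geometry helpers.

The arena is periodic in both horizontal directions: coordinates live on a
torus of circumference ``L`` and all displacements between agents use the
minimal image convention.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DIRECTIONS",
    "wrap",
    "toroidal_offset",
    "periodic_centroid",
    "periodic_distance",
]

#: The eight horizontal lattice moves, counter-clockwise from +x.
DIRECTIONS = np.array(
    [[1, 0], [1, 1], [0, 1], [-1, 1], [-1, 0], [-1, -1], [0, -1], [1, -1]],
    dtype=np.int64,
)


def wrap(coord, L: int):
    """Map pixel coordinates into ``[0, L)`` component-wise.

    Idempotent; works on scalars, pairs and arrays.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    arr = np.asarray(coord)
    out = np.mod(arr, L)
    if np.isscalar(coord):
        return int(out)
    if isinstance(coord, tuple):
        return tuple(int(v) for v in out)
    return out


def toroidal_offset(a, b, L: int):
    """Minimal-image displacement ``b - a`` on the ``L``-torus.

    Each component of the result lies in ``(-L/2, L/2]`` (the two equally
    distant images at exactly half the arena resolve to the positive one).
    Works on real as well as integer coordinates; broadcasting follows
    numpy rules.
    """
    a_arr = np.asarray(a)
    b_arr = np.asarray(b)
    integer_in = a_arr.dtype.kind in "iu" and b_arr.dtype.kind in "iu"
    half = L / 2.0
    d = half - np.mod(half - (b_arr.astype(float) - a_arr.astype(float)), L)
    if integer_in:
        d = np.round(d).astype(np.int64)
    if isinstance(a, tuple) and d.shape == (2,):
        return tuple(int(v) if integer_in else float(v) for v in d)
    return d


def periodic_distance(a, b, L: int) -> float:
    """Euclidean distance under the minimal image convention."""
    d = np.asarray(toroidal_offset(a, b, L), dtype=float)
    return float(np.sqrt(np.sum(d * d, axis=-1)))

def periodic_centroid(coords: np.ndarray, L: int) -> np.ndarray:
    """Center of a point set on the torus via the circular mean.

    Each axis is mapped to an angle on the unit circle, unit vectors are
    averaged and the mean angle mapped back to a coordinate, so a cluster
    straddling the periodic seam gets a center inside the cluster rather
    than at the far side of the arena.  If the mean vector of an axis
    vanishes (perfectly balanced set) the plain arithmetic mean is used
    for that axis.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("periodic_centroid of an empty point set")
    out = np.empty(2, dtype=float)
    for ax in range(2):
        theta = coords[:, ax] * (2.0 * np.pi / L)
        sv = np.sin(theta).mean()
        cv = np.cos(theta).mean()
        if np.hypot(sv, cv) < 1e-12:
            out[ax] = coords[:, ax].mean()
        else:
            out[ax] = np.mod(np.arctan2(sv, cv), 2.0 * np.pi) * (L / (2.0 * np.pi))
    return out
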