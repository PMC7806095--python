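"""Lattice world state: locked-stack height field plus per-agent records.

The arena is an ``L x L x inf`` cubic lattice.  Locked agents at a pixel
form a contiguous column from the floor, so the whole locked structure is
captured by an integer height field.  Each free agent stands on the
surface of its pixel, at ``z == height[x, y]``; at most one free agent
per pixel.  ``covered`` is not stored — it is a function of occupancy
(a locked agent with any agent in the voxel directly above it) and is
recomputed on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import SimulationParams

__all__ = ["FREE", "LOCKED", "COVERED", "WorldState"]

FREE = 0
LOCKED = 1
COVERED = 2  # derived tag, only ever returned by WorldState.states()


@dataclass
class WorldState:
    """Complete state of the simulation at one time step.

    Attributes
    ----------
    L:
        Arena side length.
    height:
        ``(L, L)`` int64 array; ``height[x, y]`` is the number of locked
        (including covered) agents stacked at pixel ``(x, y)``.
    free_occ:
        ``(L, L)`` int64 array holding the id of the free agent standing
        on each pixel's surface, or ``-1``.
    agent_x, agent_y, agent_z:
        Per-agent voxel coordinates.  A free agent has
        ``agent_z == height[x, y]``; a locked agent sits inside its
        column at ``agent_z < height[x, y]``.
    locked:
        Per-agent boolean; ``False`` means free.
    t:
        Current time step.
    """

    L: int
    height: np.ndarray
    free_occ: np.ndarray
    agent_x: np.ndarray
    agent_y: np.ndarray
    agent_z: np.ndarray
    locked: np.ndarray
    t: int = 0

    # ------------------------------------------------------------------
    @classmethod
    def initialize(cls, params: SimulationParams, rng: np.random.Generator) -> "WorldState":
        """Scatter ``N`` free agents on distinct pixels of the empty floor."""
        L, N = params.L, params.N
        if N > L * L:
            raise ValueError(f"cannot place N={N} agents on {L * L} pixels")
        flat = rng.choice(L * L, size=N, replace=False)
        x, y = np.divmod(flat, L)
        world = cls(
            L=L,
            height=np.zeros((L, L), dtype=np.int64),
            free_occ=np.full((L, L), -1, dtype=np.int64),
            agent_x=x.astype(np.int64),
            agent_y=y.astype(np.int64),
            agent_z=np.zeros(N, dtype=np.int64),
            locked=np.zeros(N, dtype=bool),
            t=0,
        )
        world.free_occ[world.agent_x, world.agent_y] = np.arange(N)
        return world

    @classmethod
    def empty(cls, L: int) -> "WorldState":
        """An arena with no agents at all (metric fixtures)."""
        return cls(
            L=L,
            height=np.zeros((L, L), dtype=np.int64),
            free_occ=np.full((L, L), -1, dtype=np.int64),
            agent_x=np.zeros(0, dtype=np.int64),
            agent_y=np.zeros(0, dtype=np.int64),
            agent_z=np.zeros(0, dtype=np.int64),
            locked=np.zeros(0, dtype=bool),
            t=0,
        )

    # ------------------------------------------------------------------
    @property
    def N(self) -> int:
        return self.agent_x.size

    def covered_mask(self) -> np.ndarray:
        """Boolean mask of covered agents.

        A locked agent is covered iff the voxel directly above it is
        occupied: either another locked agent (``z < height - 1``) or a
        free agent standing on top of the stack (``z == height - 1`` and
        the pixel's surface is taken).
        """
        h_here = self.height[self.agent_x, self.agent_y]
        below_top = self.agent_z < h_here - 1
        top_with_free = (self.agent_z == h_here - 1) & (
            self.free_occ[self.agent_x, self.agent_y] >= 0
        )
        return self.locked & (below_top | top_with_free)

    def states(self) -> np.ndarray:
        """Per-agent state tags: FREE, LOCKED (uncovered) or COVERED."""
        out = np.where(self.locked, LOCKED, FREE).astype(np.int8)
        out[self.covered_mask()] = COVERED
        return out

    def counts(self) -> dict:
        s = self.states()
        return {
            "free": int(np.sum(s == FREE)),
            "locked": int(np.sum(s == LOCKED)),
            "covered": int(np.sum(s == COVERED)),
        }

    def copy(self) -> "WorldState":
        return WorldState(
            L=self.L,
            height=self.height.copy(),
            free_occ=self.free_occ.copy(),
            agent_x=self.agent_x.copy(),
            agent_y=self.agent_y.copy(),
            agent_z=self.agent_z.copy(),
            locked=self.locked.copy(),
            t=self.t,
        )

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Assert every structural invariant; raise AssertionError if broken.

        Checks conservation, single occupancy, stack contiguity, the
        free-agent surface rule and the height bookkeeping.
        """
        L, N = self.L, self.N
        assert self.height.shape == (L, L) and self.free_occ.shape == (L, L)
        assert np.all(self.height >= 0), "negative stack height"
        assert np.all((self.agent_x >= 0) & (self.agent_x < L))
        assert np.all((self.agent_y >= 0) & (self.agent_y < L))
        assert np.all(self.agent_z >= 0), "agent below the floor"

        free_ids = np.flatnonzero(~self.locked)
        # one free agent per pixel, each registered on the grid
        fx, fy = self.agent_x[free_ids], self.agent_y[free_ids]
        assert len({(int(a), int(b)) for a, b in zip(fx, fy)}) == free_ids.size, (
            "two free agents share a pixel"
        )
        assert np.all(self.free_occ[fx, fy] == free_ids), "free_occ grid out of sync"
        assert np.sum(self.free_occ >= 0) == free_ids.size
        # free agents stand exactly on the surface
        assert np.all(self.agent_z[free_ids] == self.height[fx, fy]), (
            "free agent not on its pixel surface"
        )

        # locked stacks are contiguous columns 0..height-1
        locked_ids = np.flatnonzero(self.locked)
        assert int(self.height.sum()) == locked_ids.size, (
            "sum(height) != number of locked+covered agents"
        )
        per_pixel: dict = {}
        for aid in locked_ids:
            key = (int(self.agent_x[aid]), int(self.agent_y[aid]))
            per_pixel.setdefault(key, []).append(int(self.agent_z[aid]))
        for (x, y), zs in per_pixel.items():
            assert sorted(zs) == list(range(self.height[x, y])), (
                f"non-contiguous stack at {(x, y)}"
            )
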