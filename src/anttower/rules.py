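"""Behavioral rules of the tower-building model, one function per rule.

These are the readable reference implementations operating on a
:class:`~anttower.world.WorldState` with an injectable
``numpy.random.Generator``.  They define the model's semantics and are
what the unit and property tests exercise directly; long simulations run
the same rules through the fused numba kernel in
:mod:`anttower.engine` (cross-checked in the test suite).

A time step is::

    proposals = propose_moves(world, params, rng)   # pre-move snapshot
    resolve_moves(world, proposals, rng)            # random order, climb +
                                                    # collision handling
    update_states(world, params, rng)               # lock / unlock draws

Locking follows ``P_l = min(Psl + knl * N_n, 1)`` with ``N_n`` the
number of locked neighbors among the 26 Moore voxels; movement follows
``v = v_random + (c / n_i) * sum_j (x_j - x_i)`` over all ``n_i``
occupied neighbor voxels, projected to the horizontal plane, quantized
to the best-aligned lattice move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DIRECTIONS
from .params import SimulationParams
from .world import WorldState

__all__ = [
    "MoveProposal",
    "lock_probability",
    "neighborhood",
    "attraction_velocity",
    "select_move",
    "propose_moves",
    "resolve_moves",
    "update_states",
    "step",
]


def lock_probability(n_locked: int, params: SimulationParams) -> float:
    """Locking probability of a free agent with ``n_locked`` locked neighbors.

    ``min(Psl + knl * n_locked, 1)``: a spontaneous baseline plus a
    linear neighbor term, clamped to a probability.
    """
    if n_locked < 0:
        raise ValueError(f"n_locked must be >= 0, got {n_locked}")
    if n_locked > 26:
        raise ValueError(f"n_locked cannot exceed 26, got {n_locked}")
    return min(params.Psl + params.knl * n_locked, 1.0)


def neighborhood(world: WorldState, agent_id: int):
    """Occupancy of the 26 Moore voxels around an agent.

    Returns ``(n_all, n_locked, offsets)``: counts of occupied neighbor
    voxels of any state and of locked/covered state, plus the list of 3D
    integer offsets ``(dx, dy, dz)`` of every occupied neighbor voxel.
    Horizontal wrapping is periodic; voxels below the floor are vacant.
    """
    L = world.L
    x = int(world.agent_x[agent_id])
    y = int(world.agent_y[agent_id])
    z = int(world.agent_z[agent_id])
    n_all = 0
    n_locked = 0
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            nx, ny = (x + dx) % L, (y + dy) % L
            h = int(world.height[nx, ny])
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                zz = z + dz
                if zz < 0:
                    continue
                if zz < h:
                    n_all += 1
                    n_locked += 1
                    offsets.append((dx, dy, dz))
                elif zz == h:
                    occ = int(world.free_occ[nx, ny])
                    if occ >= 0 and occ != agent_id:
                        n_all += 1
                        offsets.append((dx, dy, dz))
    return n_all, n_locked, offsets


def attraction_velocity(
    agent_id: int,
    world: WorldState,
    params: SimulationParams,
    rng: np.random.Generator,
    v_random: np.ndarray | None = None,
) -> np.ndarray:
    """Velocity of a free agent: random unit vector plus neighbor attraction.

    The random part is a unit vector at an angle uniform on ``[0, 2pi)``
    (pass ``v_random`` to pin it in tests).  The attraction part is
    ``(c / n_i)`` times the sum of the horizontal components of the
    offsets to all ``n_i`` occupied neighbor voxels, of any agent state;
    with no neighbors it vanishes and the motion is a pure random walk.
    """
    if v_random is None:
        theta = rng.uniform(0.0, 2.0 * np.pi)
        v_random = np.array([np.cos(theta), np.sin(theta)])
    v = np.asarray(v_random, dtype=float).copy()
    n_all, _n_locked, offsets = neighborhood(world, agent_id)
    if n_all > 0:
        horiz = np.array([[dx, dy] for dx, dy, _dz in offsets], dtype=float)
        v += params.c * horiz.sum(axis=0) / n_all
    return v


def select_move(v, rng: np.random.Generator | None = None):
    """Quantize a velocity to the best-aligned of the 8 lattice moves.

    Returns an ``(dx, dy)`` pair, or ``(0, 0)`` (stay) for a zero
    velocity.  The chosen move maximizes the cosine with ``v``; exact
    ties are broken uniformly at random.
    """
    v = np.asarray(v, dtype=float)
    if np.any(np.isnan(v)):
        raise ValueError("velocity has NaN components")
    if v[0] == 0.0 and v[1] == 0.0:
        return (0, 0)
    norms = np.sqrt((DIRECTIONS**2).sum(axis=1))
    scores = (DIRECTIONS @ v) / norms
    best = scores.max()
    ties = np.flatnonzero(scores == best)
    if ties.size == 1:
        k = ties[0]
    else:
        if rng is None:
            rng = np.random.default_rng()
        k = ties[rng.integers(ties.size)]
    return (int(DIRECTIONS[k, 0]), int(DIRECTIONS[k, 1]))


@dataclass
class MoveProposal:
    """One free agent's intended move for the current step."""

    agent_id: int
    current: tuple
    target: tuple  # == current for a stay proposal
    resolved: tuple | None = None  # filled by resolve_moves


def propose_moves(
    world: WorldState, params: SimulationParams, rng: np.random.Generator
) -> list:
    """Intended moves of every free agent, all from the pre-move snapshot."""
    L = world.L
    proposals = []
    for aid in np.flatnonzero(~world.locked):
        aid = int(aid)
        v = attraction_velocity(aid, world, params, rng)
        dx, dy = select_move(v, rng)
        x, y = int(world.agent_x[aid]), int(world.agent_y[aid])
        proposals.append(
            MoveProposal(aid, (x, y), ((x + dx) % L, (y + dy) % L))
        )
    return proposals


def resolve_moves(
    world: WorldState,
    proposals: list,
    rng: np.random.Generator,
    order: np.ndarray | None = None,
) -> WorldState:
    """Apply proposals one agent at a time in a uniformly-random order.

    Rules, evaluated at each agent's processing moment: a move whose
    target surface is more than one voxel above the mover's current
    voxel is rejected (the agent stays; downward moves of any distance
    are fine); a target pixel whose surface voxel holds a free agent
    triggers the collision fallback — a uniform choice among the 8
    pixels adjacent to the target that are unoccupied and climbable from
    the mover's current voxel, staying put if none qualifies.  Heights
    only change in the locking phase, so mid-phase only free-agent
    occupancy evolves.  Mutates and returns ``world``.

    ``order`` (a permutation of ``range(len(proposals))``) can be pinned
    for exhaustive order-dependence tests.
    """
    ids = [p.agent_id for p in proposals]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate agent ids in proposals")
    L = world.L
    if order is None:
        order = rng.permutation(len(proposals))
    for k in order:
        p = proposals[int(k)]
        aid = p.agent_id
        x, y = int(world.agent_x[aid]), int(world.agent_y[aid])
        tx, ty = p.target
        if (tx, ty) == (x, y):
            p.resolved = (x, y)
            continue
        h_cur = int(world.height[x, y])
        if world.height[tx, ty] > h_cur + 1:
            p.resolved = (x, y)  # climb rejected
            continue
        world.free_occ[x, y] = -1
        if world.free_occ[tx, ty] < 0:
            nx, ny = tx, ty
        else:
            cands = []
            for dx, dy in DIRECTIONS:
                ax, ay = (tx + dx) % L, (ty + dy) % L
                if world.free_occ[ax, ay] < 0 and world.height[ax, ay] <= h_cur + 1:
                    cands.append((ax, ay))
            if not cands:
                world.free_occ[x, y] = aid
                p.resolved = (x, y)
                continue
            nx, ny = cands[rng.integers(len(cands))]
        world.free_occ[nx, ny] = aid
        world.agent_x[aid] = nx
        world.agent_y[aid] = ny
        world.agent_z[aid] = world.height[nx, ny]
        p.resolved = (nx, ny)
    return world


def update_states(
    world: WorldState, params: SimulationParams, rng: np.random.Generator
) -> WorldState:
    """Lock/unlock phase on the post-move configuration.

    Every free agent locks with ``lock_probability`` of its locked
    Moore-neighbor count; every uncovered locked agent (top of its
    stack, no free agent standing on it) unlocks with probability
    ``Pu``, stepping the surface down and becoming the free occupant of
    the voxel it vacated.  All Bernoulli draws are taken against the
    same snapshot before any is applied, so newly locked agents do not
    feed their neighbors' counts until the next step.  Covered agents
    never unlock; coverage itself is derived from occupancy, so a
    covered agent whose cover departs reverts to plain locked.  Mutates
    and returns ``world``.
    """
    free_ids = np.flatnonzero(~world.locked)
    to_lock = []
    for aid in free_ids:
        aid = int(aid)
        _n_all, n_locked, _ = neighborhood(world, aid)
        if rng.random() < lock_probability(n_locked, params):
            to_lock.append(aid)
    to_unlock = []
    if params.Pu > 0.0:
        for aid in np.flatnonzero(world.locked):
            aid = int(aid)
            x, y = int(world.agent_x[aid]), int(world.agent_y[aid])
            uncovered = (
                world.agent_z[aid] == world.height[x, y] - 1
                and world.free_occ[x, y] < 0
            )
            if uncovered and rng.random() < params.Pu:
                to_unlock.append(aid)
    for aid in to_lock:
        x, y = int(world.agent_x[aid]), int(world.agent_y[aid])
        world.locked[aid] = True
        world.free_occ[x, y] = -1
        world.height[x, y] += 1
    for aid in to_unlock:
        x, y = int(world.agent_x[aid]), int(world.agent_y[aid])
        world.locked[aid] = False
        world.height[x, y] -= 1
        world.free_occ[x, y] = aid
    return world


def step(
    world: WorldState, params: SimulationParams, rng: np.random.Generator
) -> WorldState:
    """Advance one full time step: move all free agents, then lock/unlock."""
    proposals = propose_moves(world, params, rng)
    resolve_moves(world, proposals, rng)
    update_states(world, params, rng)
    world.t += 1
    return world
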