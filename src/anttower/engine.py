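"""Fused numba kernel advancing the lattice world.

The per-step update is: (1) every free agent computes its velocity — a
unit vector at a uniform random angle plus ``c`` times the mean
minimal-image horizontal displacement to its occupied Moore-neighbor
voxels — and quantizes it to the best-aligned of the 8 lattice moves
(or stays for zero velocity); (2) moves are resolved one agent at a time
in a fresh random order, with the climb rule (at most one voxel up, any
distance down) and collision fallback to a free pixel adjacent to the
contested target; (3) on the post-move configuration every free agent
locks with probability ``min(Psl + knl * n_locked_neighbors, 1)`` and
every uncovered locked agent unlocks with probability ``Pu``, all draws
taken against the same snapshot before any is applied.

The kernel mutates the arrays of a :class:`~anttower.world.WorldState`
in place.  Randomness comes from numba's internal Mersenne Twister,
seeded explicitly through :func:`seed_engine`; a fixed seeding schedule
makes whole runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["seed_engine", "advance"]

# lattice moves, counter-clockwise from +x (index 8 = stay)
_DX = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)
_DY = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)
_INV_NORM = 1.0 / np.sqrt((_DX * _DX + _DY * _DY).astype(np.float64))


@njit(cache=True)
def seed_engine(seed):
    """Seed numba's internal RNG used by all kernel randomness."""
    np.random.seed(seed)


@njit(cache=True)
def _scan_neighborhood(height, free_occ, L, x, y, z, self_id):
    """Scan the 26 Moore voxels around (x, y, z).

    Returns ``(n_all, n_locked, sum_dx, sum_dy)`` where ``n_all`` counts
    occupied neighbor voxels of any agent state, ``n_locked`` only
    locked/covered ones, and the sums accumulate the horizontal
    components of the occupied-voxel offsets (used by the attraction
    rule; vertical components are dropped).
    """
    n_all = 0
    n_locked = 0
    sum_dx = 0.0
    sum_dy = 0.0
    for dx in (-1, 0, 1):
        nx = (x + dx) % L
        for dy in (-1, 0, 1):
            ny = (y + dy) % L
            h = height[nx, ny]
            for dz in (-1, 0, 1):
                if dx == 0 and dy == 0 and dz == 0:
                    continue
                zz = z + dz
                if zz < 0:
                    continue
                if zz < h:
                    # voxel inside a locked column
                    n_all += 1
                    n_locked += 1
                    sum_dx += dx
                    sum_dy += dy
                elif zz == h:
                    occ = free_occ[nx, ny]
                    if occ >= 0 and occ != self_id:
                        n_all += 1
                        sum_dx += dx
                        sum_dy += dy
    return n_all, n_locked, sum_dx, sum_dy


@njit(cache=True)
def _select_direction(vx, vy):
    """Index of the lattice move best aligned with (vx, vy); 8 = stay.

    Maximizes the cosine with the velocity; exact ties are broken
    uniformly at random.
    """
    if vx == 0.0 and vy == 0.0:
        return 8
    best = -2.0
    n_best = 0
    first = 8
    scores = np.empty(8, dtype=np.float64)
    for k in range(8):
        scores[k] = (vx * _DX[k] + vy * _DY[k]) * _INV_NORM[k]
        if scores[k] > best:
            best = scores[k]
    for k in range(8):
        if scores[k] == best:
            n_best += 1
            if n_best == 1:
                first = k
    if n_best == 1:
        return first
    pick = int(np.random.random() * n_best)
    seen = 0
    for k in range(8):
        if scores[k] == best:
            if seen == pick:
                return k
            seen += 1
    return first


@njit(cache=True)
def _move_phase(height, free_occ, agent_x, agent_y, agent_z, free_ids, L, c):
    """Propose and resolve one movement phase for all free agents."""
    n_free = free_ids.size
    # --- proposal: everyone evaluates movement on the pre-move world
    tdir = np.empty(n_free, dtype=np.int64)
    for i in range(n_free):
        aid = free_ids[i]
        x = agent_x[aid]
        y = agent_y[aid]
        z = agent_z[aid]
        n_all, _n_locked, sdx, sdy = _scan_neighborhood(
            height, free_occ, L, x, y, z, aid
        )
        theta = np.random.random() * 2.0 * np.pi
        vx = np.cos(theta)
        vy = np.sin(theta)
        if n_all > 0:
            vx += c * sdx / n_all
            vy += c * sdy / n_all
        tdir[i] = _select_direction(vx, vy)

    # --- resolution in a fresh uniformly-random processing order
    order = np.arange(n_free)
    np.random.shuffle(order)
    cand = np.empty(8, dtype=np.int64)
    for k in range(n_free):
        i = order[k]
        d = tdir[i]
        if d == 8:
            continue
        aid = free_ids[i]
        x = agent_x[aid]
        y = agent_y[aid]
        h_cur = height[x, y]
        tx = (x + _DX[d]) % L
        ty = (y + _DY[d]) % L
        if height[tx, ty] > h_cur + 1:
            continue  # climb of more than one voxel: stay
        free_occ[x, y] = -1  # vacate; own pixel is a legal fallback
        if free_occ[tx, ty] < 0:
            nx, ny = tx, ty
        else:
            # collision: pick uniformly among free adjacent pixels of the
            # target that are climbable from the mover's current voxel
            n_cand = 0
            for j in range(8):
                ax = (tx + _DX[j]) % L
                ay = (ty + _DY[j]) % L
                if free_occ[ax, ay] < 0 and height[ax, ay] <= h_cur + 1:
                    cand[n_cand] = j
                    n_cand += 1
            if n_cand == 0:
                free_occ[x, y] = aid  # nowhere to go: stay
                continue
            j = cand[int(np.random.random() * n_cand)]
            nx = (tx + _DX[j]) % L
            ny = (ty + _DY[j]) % L
        free_occ[nx, ny] = aid
        agent_x[aid] = nx
        agent_y[aid] = ny
        agent_z[aid] = height[nx, ny]


@njit(cache=True)
def _state_phase(
    height, free_occ, agent_x, agent_y, agent_z, locked, free_ids, L, Pu, knl, Psl
):
    """Lock/unlock decisions on the post-move snapshot, then apply.

    All Bernoulli draws are taken against the configuration as it stands
    after movement; agents locking this step do not raise their
    neighbors' locked counts until the next step.  A pixel can never
    host both a lock and an unlock in the same step (a free agent on a
    stack covers its top agent).
    """
    n_free = free_ids.size
    lock_flag = np.zeros(n_free, dtype=np.bool_)
    for i in range(n_free):
        aid = free_ids[i]
        _n_all, n_locked, _sx, _sy = _scan_neighborhood(
            height, free_occ, L, agent_x[aid], agent_y[aid], agent_z[aid], aid
        )
        p_lock = Psl + knl * n_locked
        if p_lock > 1.0:
            p_lock = 1.0
        if np.random.random() < p_lock:
            lock_flag[i] = True

    n_agents = locked.size
    unlock_flag = np.zeros(n_agents, dtype=np.bool_)
    if Pu > 0.0:
        for aid in range(n_agents):
            if not locked[aid]:
                continue
            x = agent_x[aid]
            y = agent_y[aid]
            # uncovered = top of its stack with no free agent standing on it
            if agent_z[aid] == height[x, y] - 1 and free_occ[x, y] < 0:
                if np.random.random() < Pu:
                    unlock_flag[aid] = True

    for i in range(n_free):
        if lock_flag[i]:
            aid = free_ids[i]
            x = agent_x[aid]
            y = agent_y[aid]
            locked[aid] = True
            free_occ[x, y] = -1
            height[x, y] += 1  # agent_z already equals the old height
    for aid in range(n_agents):
        if unlock_flag[aid]:
            x = agent_x[aid]
            y = agent_y[aid]
            locked[aid] = False
            height[x, y] -= 1
            free_occ[x, y] = aid  # agent_z already equals the new height


@njit(cache=True)
def _advance(height, free_occ, agent_x, agent_y, agent_z, locked, L, n_steps, c, Pu, knl, Psl):
    for _ in range(n_steps):
        free_ids = np.flatnonzero(~locked)
        _move_phase(height, free_occ, agent_x, agent_y, agent_z, free_ids, L, c)
        _state_phase(
            height, free_occ, agent_x, agent_y, agent_z, locked, free_ids, L, Pu, knl, Psl
        )


def advance(world, params, n_steps: int, chunk_seed: int) -> None:
    """Advance ``world`` in place by ``n_steps`` under ``params``.

    ``chunk_seed`` seeds the kernel RNG for this call; the caller owns
    the seeding schedule (see :class:`anttower.simulator.Simulator`).
    """
    seed_engine(np.uint32(chunk_seed))
    _advance(
        world.height,
        world.free_occ,
        world.agent_x,
        world.agent_y,
        world.agent_z,
        world.locked,
        world.L,
        n_steps,
        float(params.c),
        float(params.Pu),
        float(params.knl),
        float(params.Psl),
    )
    world.t += n_steps
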