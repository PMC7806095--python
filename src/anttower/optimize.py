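"""Tower-shape optimization: cost function and CMA-ES search.

The cost of a parameter set rewards towers that are both large and
tall::

    f = (1 - N_tower / N_max) + max(0, 1 - h_tower / h_max)

with ``N_tower`` and ``h_tower`` taken from the largest tower at the
end of a (short, 50,000-step) simulation, ``N_max`` the number of
agents in the simulation and ``h_max`` a prescribed height ceiling
(default 14; towers at or above it zero out the height term).  The
search minimizes the mean cost over three replicate simulations per
candidate ``(Pu, knl, c)`` triple, ten candidates per CMA-ES iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cmaes import CMAES
from .dynamics import replicate_seed
from .params import SimulationParams
from .simulator import run

__all__ = [
    "DEFAULT_H_MAX",
    "CostEvaluation",
    "cost",
    "evaluate_candidate",
    "cmaes_search",
]

DEFAULT_H_MAX = 14
#: search box for (Pu, knl, c); samples outside are clamped with a penalty
DEFAULT_BOUNDS = ((0.0, 1.0), (0.0, 1.0), (0.0, 4.0))


def cost(n_tower: int, h_tower: int, n_max: int, h_max: int = DEFAULT_H_MAX) -> float:
    """Tower cost; 0 for a full-enrollment, full-height tower, 2 for none."""
    if n_max <= 0 or h_max <= 0:
        raise ValueError("n_max and h_max must be positive")
    if not 0 <= n_tower <= n_max:
        raise ValueError(f"n_tower={n_tower} outside [0, {n_max}]")
    if h_tower < 0:
        raise ValueError("h_tower must be >= 0")
    return (1.0 - n_tower / n_max) + max(0.0, 1.0 - h_tower / h_max)


@dataclass(frozen=True)
class CostEvaluation:
    """Mean cost of one parameter triple over replicate trials."""

    f: float  # mean cost over trials, in [0, 2]
    per_trial: tuple  # (f, N_tower, h_tower) per trial
    N_max: int
    h_max: int

    @property
    def best_trial(self) -> tuple:
        return min(self.per_trial, key=lambda t: t[0])


def evaluate_candidate(
    triple,
    base: SimulationParams,
    trials: int = 3,
    steps: int = 50_000,
    h_max: int = DEFAULT_H_MAX,
    seed: int | None = None,
) -> CostEvaluation:
    """Mean tower cost of a ``(Pu, knl, c)`` triple over replicate runs.

    Each trial runs an independent simulation (child seeds derived from
    ``seed``, default the base params seed) for ``steps`` steps and
    evaluates the cost on its final largest tower.
    """
    Pu, knl, c = (float(v) for v in triple)
    if seed is None:
        seed = base.seed
    per_trial = []
    for r in range(trials):
        params = base.replace(
            Pu=Pu, knl=knl, c=c, steps=steps,
            seed=replicate_seed(seed, r),
        )
        s = run(params).final_largest
        per_trial.append((cost(s.n_agents, s.height, base.N, h_max),
                          s.n_agents, s.height))
    return CostEvaluation(
        f=float(np.mean([t[0] for t in per_trial])),
        per_trial=tuple(per_trial),
        N_max=base.N,
        h_max=h_max,
    )


def cmaes_search(
    base: SimulationParams,
    population: int = 10,
    max_iter: int = 30,
    target_cost: float = 0.02,
    trials: int = 3,
    steps: int = 50_000,
    h_max: int = DEFAULT_H_MAX,
    bounds=DEFAULT_BOUNDS,
    sigma0: float = 0.3,
    seed: int = 0,
    penalty_weight: float = 10.0,
):
    """CMA-ES search over ``(Pu, knl, c)`` for the cheapest tower.

    The optimizer works in box-normalized coordinates (the search box
    mapped to the unit cube, mean started at its center).  Out-of-box
    samples are clamped before simulation and charged a quadratic
    penalty, keeping every evaluated parameter set valid.  The search
    stops when the best (unpenalized) mean cost drops to
    ``target_cost`` or after ``max_iter`` iterations.

    Returns ``(best, history)``: ``best`` a dict with the winning
    ``Pu/knl/c``, its :class:`CostEvaluation` and the iteration it
    appeared in; ``history`` a per-candidate DataFrame (iteration,
    parameters, cost, penalty, best-so-far).
    """
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    es = CMAES(x0=np.full(3, 0.5), sigma0=sigma0, popsize=population, seed=seed)

    rows = []
    best = None
    best_f = np.inf
    for it in range(max_iter):
        us = es.ask()
        fs = np.empty(len(us))
        for j, u in enumerate(us):
            u_cl = np.clip(u, 0.0, 1.0)
            penalty = penalty_weight * float(np.sum((u - u_cl) ** 2))
            triple = lo + u_cl * (hi - lo)
            ev = evaluate_candidate(
                triple, base, trials=trials, steps=steps, h_max=h_max,
                seed=replicate_seed(seed, 1000 * it + j),
            )
            fs[j] = ev.f + penalty
            if ev.f < best_f:
                best_f = ev.f
                best = dict(Pu=triple[0], knl=triple[1], c=triple[2],
                            evaluation=ev, iteration=it)
            rows.append(dict(iteration=it, Pu=triple[0], knl=triple[1],
                             c=triple[2], f=ev.f, penalty=penalty,
                             best_so_far=best_f))
        es.tell(us, fs)
        if best_f <= target_cost:
            break
    return best, pd.DataFrame(rows)
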