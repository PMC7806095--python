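"""Simulation parameter container.

All model constants live in one frozen dataclass so that a run is fully
specified by a :class:`SimulationParams` instance plus nothing else.  The
agent density ``rho = N / L**2`` is always derived, never stored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

__all__ = ["SimulationParams"]

#: probability per step that an isolated free agent locks spontaneously,
#: seeding a new tower (1/20,000 in all standard runs).
DEFAULT_PSL = 1.0 / 20_000.0


@dataclass(frozen=True)
class SimulationParams:
    """Constants of one tower-building simulation.

    Parameters
    ----------
    L:
        Side length of the square arena in voxels (the arena is
        ``L x L x inf``, periodic horizontally, solid floor below).
    N:
        Number of agents.  Each agent occupies exactly one unit voxel.
    Pu:
        Per-step unlock probability of an uncovered locked agent.
    knl:
        Neighbor-locking factor: each locked agent among the 26 Moore
        neighbors adds ``knl`` to the locking probability.  ``1/knl`` is
        the neighbor count that guarantees locking.
    Psl:
        Spontaneous locking probability per step (tower seeding).
    c:
        Attraction-to-randomness ratio of the movement rule: the agent
        velocity is a unit random vector plus ``c`` times the mean
        horizontal displacement towards its occupied neighbor voxels.
    steps:
        Number of time steps to simulate.
    seed:
        Seed for all randomness of the run.
    sample_interval:
        Stride, in steps, at which time series and snapshots are recorded.

    The voxel edge is the unit of length (``l == 1``) and one step the
    unit of time; all derived quantities (diffusion coefficients, tower
    diameters) are expressed in these units.
    """

    L: int = 100
    N: int = 1000
    Pu: float = 0.0
    knl: float = 0.0
    Psl: float = DEFAULT_PSL
    c: float = 0.0
    steps: int = 500_000
    seed: int = 0
    sample_interval: int = 250

    def __post_init__(self) -> None:
        if int(self.L) != self.L or self.L < 3:
            raise ValueError(f"L must be an integer >= 3, got {self.L}")
        if int(self.N) != self.N or self.N < 1:
            raise ValueError(f"N must be an integer >= 1, got {self.N}")
        if self.N > self.L**2:
            raise ValueError(
                f"N={self.N} exceeds L^2={self.L**2}: every free agent "
                "needs a distinct surface pixel at t=0"
            )
        if not 0.0 <= self.Pu <= 1.0:
            raise ValueError(f"Pu must lie in [0, 1], got {self.Pu}")
        if self.knl < 0.0:
            raise ValueError(f"knl must be >= 0, got {self.knl}")
        if not 0.0 <= self.Psl <= 1.0:
            raise ValueError(f"Psl must lie in [0, 1], got {self.Psl}")
        if self.c < 0.0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if self.steps < 0:
            raise ValueError(f"steps must be >= 0, got {self.steps}")
        if self.sample_interval < 1:
            raise ValueError(
                f"sample_interval must be >= 1, got {self.sample_interval}"
            )

    @property
    def rho(self) -> float:
        """Agent density ``N / L**2`` (agents per arena pixel)."""
        return self.N / float(self.L**2)

    def replace(self, **changes) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
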