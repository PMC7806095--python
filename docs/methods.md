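# Methods

## Model

Agents occupy unit voxels of an `L × L × ∞` cubic lattice with periodic
horizontal boundaries and a solid floor. An agent is *free* (mobile on
the surface defined by the locked structure), *locked* (stationary,
climbable), or *covered* (locked with any agent in the voxel directly
above; covered agents cannot unlock). Locked agents at a pixel always
form a contiguous column from the floor, so the structure is fully
described by an integer height field; each free agent stands at
`z = h(x, y)` of its pixel and at most one free agent occupies a pixel.

Each time step has two phases. First, all free agents *simultaneously*
evaluate their intended move from the current configuration: the
velocity is a unit vector at a uniform random angle plus
`(c / n_i) Σ_j Δx_j`, the sum running over all `n_i` occupied voxels of
the agent's 26-voxel Moore neighborhood (any agent state) with `Δx_j`
the minimal-image *horizontal* projection of the offset; the agent
targets the one of its 8 horizontal neighbor pixels best aligned (by
cosine) with the velocity, staying put only for an exactly zero vector
(ties broken uniformly). Moves are then applied one agent at a time in
a fresh uniformly-random order: a move to a pixel whose surface is more
than one voxel above the mover's current voxel is refused; moves down
any distance are allowed; if the destination surface is occupied by a
free agent, the mover instead picks uniformly among the 8 pixels
adjacent to the target whose surface is unoccupied *and* climbable from
the mover's current voxel, staying put when none qualifies.

Second, on the post-move configuration, every free agent locks with
probability `min(P_sl + k_nl · N_n, 1)` (`N_n` = locked/covered Moore
neighbors) and every uncovered locked agent unlocks with probability
`P_u`, all Bernoulli draws taken against the same snapshot before any
is applied — newly locked agents do not raise their neighbors' counts
until the next step, and the two kinds of event can never collide on a
pixel (a pixel hosting a locking free agent has a covered stack top).
An unlocking agent becomes the free occupant of the surface voxel it
vacated.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| `L` | arena side | 100 | voxels |
| `N` | agents | 1000 | — (density ρ = N/L²) |
| `Pu` | unlock probability | 0 | per step |
| `knl` | per-neighbor locking increment | 0 | per neighbor |
| `Psl` | spontaneous locking | 1/20,000 | per step |
| `c` | attraction-to-randomness ratio | 0 | — |
| `sample_interval` | recording stride | 250 | steps |

The voxel edge and the time step are the units of length and time; all
derived quantities (diameters, diffusion coefficients in pixels²/step)
inherit them. Standard full-scale runs use 500,000 steps, at which
nearly all parameter sets settle (steady state: largest-tower size
within ±5% of N over the trailing 100,000 steps).

## Interpretation choices

Places where the behavioral rules admit more than one reading, decided
once and fixed:

- **Random velocity** is a 2D unit vector at a uniform angle, so `c`
  is literally the attraction-to-randomness magnitude ratio.
- **Attraction geometry**: neighbor offsets are projected to the
  horizontal plane before summing (motion is two-dimensional along the
  surface); voxels directly above/below contribute to `n_i` but not to
  the direction.
- **Collision blocking**: any free agent currently on the destination
  pixel blocks, whether or not it has already been processed this
  step. This guarantees single occupancy at every instant; the
  alternative (only already-moved agents block) can strand two agents
  on one pixel.
- **Collision fallback** pixels must satisfy the climb rule from the
  mover's *original* voxel, so a collision can never teleport an agent
  up a cliff; the mover's own vacated pixel is a legal fallback.
- **Coverage is recomputed from occupancy** every step: a covered
  agent whose cover departs reverts to plain locked and may unlock
  thereafter.
- **Initialization**: `N` free agents on uniformly random distinct
  floor pixels.
- **Wrap-aware analysis**: tower components merge across the periodic
  boundary, and tower centers are periodic centroids (circular mean per
  axis), consistent with minimal-image distances in the dynamics.

## Analyses

**Tower metrics.** Towers are 8-connected components of the nonzero
height map (scipy connected-component labeling plus union-find across
the two periodic seams). A tower's agent count includes free agents
standing on its footprint; height is the maximum stack height;
equivalent diameter is `2√(area/π)`; the aspect ratio divides the two.
Runs report the tower holding the most agents.

**Tracking and diffusion.** Height maps sampled every 250 steps are
labeled and matched frame-to-frame by footprint overlap (> 0.3 of the
smaller footprint; unmatched towers fall back to the nearest center
within 5 pixels). Merges and splits conservatively end the tracks
involved and open new ones, so no trajectory mixes towers across a
merge. Centers are unwrapped by accumulating minimal-image
displacements. `MSD(t) = (1/(T−t)) Σ_{t0} |x(t+t0) − x(t0)|²` is
fitted by unweighted least squares (the (0,0) point included) over lags
`{0, 250, …, 12,500}` steps on the first 37,500 steps of each
trajectory; `D` is half the slope, and condition-level values are the
unweighted mean over all fittable tracks.

**Phase transition.** The critical attraction `c*` of a condition is
the smallest grid value of `c` whose mean final largest tower reaches
100 agents.

**Optimization.** Candidate `(Pu, knl, c)` triples are scored by the
mean over three 50,000-step trials of
`f = (1 − N_tower/N_max) + max(0, 1 − h_tower/h_max)`, `h_max = 14`.
The CMA-ES driver (a self-contained numpy implementation with rank-1
plus rank-μ covariance updates and cumulative step-size adaptation,
validated on quadratic test functions) samples 10 candidates per
iteration in the box `Pu, knl ∈ [0,1]`, `c ∈ [0,4]` (box-normalized
coordinates; out-of-box samples are clamped and penalized
quadratically) and stops at mean cost ≤ 0.02 or 30 iterations.

## Implementation and numerics

The rule set exists twice by design: readable numpy/Python functions
with injectable RNG (`anttower.rules`) define the semantics and carry
the unit tests, and a fused numba kernel (`anttower.engine`) executes
identical rules at ~10⁷ agent-steps per second for production runs.
The two paths are cross-checked statistically (locked-fraction
ensembles), against closed forms (the empirical locking hazard matches
`min(Psl + knl·N_n, 1)` in a trapped-agent fixture), and through
invariant audits at every step. Runs are bit-reproducible for a fixed
package environment: each recording chunk reseeds the kernel RNG from
the run seed and a chunk counter, and sweep/trial child seeds derive
from `numpy.random.SeedSequence` spawn keys. Direction quantization
breaks exact cosine ties uniformly at random (a measure-zero event
under the continuous random angle); a zero velocity means "stay".

## Problem sizes

Full-scale reference conditions use 10 replicates × 500,000 steps per
parameter set; the package's own end-to-end checks and
`scripts/acceptance.py` run desk-scale versions chosen once: 3 trials ×
50,000 steps at the optimized parameter set (its own protocol); 5
replicates × 150,000 steps for the post-transition cells `c = 1.06`
and `c = 1.0` (nucleation completes within the first few thousand
steps; ripening continues, so these report a modest undercount of the
500,000-step sizes); 5 replicates × 200,000 steps for the two
no-attraction cells; and for the density trend 2 replicates × 60,000
steps on the attraction grid {0.75, 1.0, 1.5} at ρ ∈ {0.05, 0.1, 0.2}.

## Synthetic data and limitations

All inputs are generated by the simulator itself; nothing is fitted to
animal data. The model abstracts away structural stability and load
limits (agents have unlimited strength), pheromone signaling, agent
heterogeneity, solid walls and the support rod of laboratory
experiments, and the viscoelastic mechanics of real ant aggregations —
passing tests therefore establish properties of the rule set, not of
live-ant behavior. Near the phase transition the model shows genuine
critical slowing down: nucleation times vary by orders of magnitude
across seeds, so desk-scale means at `c ≈ 1` carry large Monte-Carlo
spread. Diffusion estimates assume tower motion is Brownian; ballistic
or intermittent motion would bias the linear MSD fit.
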