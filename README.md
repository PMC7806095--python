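# anttower

Agent-based lattice model of collective tower building, inspired by the
towers that fire ants (*Solenopsis invicta*) assemble out of their own
bodies during floods. The package is for researchers in collective
behavior and swarm robotics who want a reproducible simulator of
self-assembly from purely local rules, together with the analysis stack
that characterizes it: tower geometry metrics, phase-transition
parameter sweeps, tower-motion diffusion estimation, and evolutionary
optimization of tower size and height.

## The model

`N` agents live on an `L × L × ∞` cubic lattice (unit voxels, periodic
horizontal boundaries, solid floor). Locked agents stack into columns,
so the built structure is a height field `h(x, y)`; each free agent
walks on the surface. Per time step:

1. **Move.** Every free agent senses its 26 Moore-neighbor voxels and
   sets a velocity

   `v_i = v_random + (c / n_i) · Σ_j (x_j − x_i)`,

   a unit vector at a uniform random angle plus attraction toward the
   `n_i` occupied neighbor voxels (horizontal components, minimal
   image). It steps to the lattice direction best aligned with `v_i`.
   Moves are resolved in random order: climbing more than one voxel up
   is refused, contested pixels push the latecomer to a free adjacent
   pixel, descents are unrestricted.
2. **Lock/unlock.** A free agent locks with probability
   `P_l = min(P_sl + k_nl · N_n, 1)` where `N_n` is its number of
   locked neighbors (`P_sl = 1/20,000` seeds new towers). An uncovered
   locked agent unlocks with probability `P_u`; covered agents (another
   agent directly above) never unlock.

Towers are 8-connected components of the nonzero height map (wrapped
across the boundary). The reported tower is the one holding the most
agents; its aspect ratio is `height / (2√(area/π))`. Tower centers
perform an effective Brownian motion quantified by `MSD = 2 D t`, and a
cost function

`f = (1 − N_tower/N_max) + max(0, 1 − h_tower/h_max)` with `h_max = 14`

drives a CMA-ES search over `(P_u, k_nl, c)` for towers that are both
large and tall.

## Worked example

```python
from anttower import SimulationParams, run

params = SimulationParams(L=100, N=1000, Pu=0.938, knl=0.029, c=2.56,
                          steps=50_000, seed=3)
res = run(params)
s = res.final_largest
print(f"largest tower: {s.n_agents} agents, height {s.height}, "
      f"aspect ratio {s.aspect_ratio:.2f}")
```

prints:

```
largest tower: 968 agents, height 15, aspect ratio 1.14
```

i.e. at the optimized parameter set — near-certain unlocking, weak
neighbor locking, strong attraction — 97% of the 1,000 agents end up in
a single tower 15 layers tall within 50,000 steps. (This parameter set
is bistable: roughly a quarter of seeds instead leave two towers of
~500 agents each at 50,000 steps.) The same run from the shell:

```bash
anttower simulate --L 100 --N 1000 --Pu 0.938 --knl 0.029 --c 2.56 \
    --steps 50000 --seed 3 --outdir out/opt
```

writes `out/opt/series.csv` (largest-tower time series), the final
state, and a JSON manifest. `anttower sweep`, `anttower diffusion` and
`anttower optimize` expose the parameter-grid, tower-tracking/diffusion
and CMA-ES pipelines the same way.

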