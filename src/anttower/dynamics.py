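"""Time-series analyses: parameter sweeps, phase-transition onset, tower
tracking, mean squared displacement and diffusion coefficients.

Tower motion is treated as a 2D Brownian walk of the tower's center of
area: ``MSD(t) = 2 D t`` with
``MSD(t) = (1/(T - t)) * sum_{t0} |x(t + t0) - x(t0)|^2``, fit by
ordinary least squares over lags ``{0, 250, ..., 12500}`` steps using
the first 37,500 steps of each trajectory; ``D`` is half the fitted
slope, in pixels^2 per step.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .geometry import periodic_centroid, periodic_distance, toroidal_offset
from .params import SimulationParams
from .simulator import run

__all__ = [
    "SweepSpec",
    "run_sweep",
    "critical_attraction",
    "TowerTrajectory",
    "track_towers",
    "msd",
    "DiffusionEstimate",
    "diffusion_coefficient",
    "mean_diffusion",
    "run_diffusion_analysis",
]

# defaults of the tracking/diffusion protocol
SAMPLE_STRIDE = 250  # steps between frames
MSD_MAX_LAG = 12_500  # largest fitted lag, steps
FIT_WINDOW = 37_500  # trajectory truncation for the fit, steps
ONSET_THRESHOLD = 100  # agents: largest tower at the transition onset


@dataclass(frozen=True)
class SweepSpec:
    """Grid of simulation conditions for a parameter sweep.

    Density is swept through ``N`` at fixed ``L``.  Each grid cell is
    run ``replicates`` times with child seeds derived deterministically
    from ``seed``.
    """

    Pu: tuple = (0.0,)
    knl: tuple = (0.0,)
    c: tuple = (0.0,)
    N: tuple = (1000,)
    L: int = 100
    replicates: int = 10
    steps: int = 500_000
    Psl: float = 1.0 / 20_000.0
    seed: int = 0
    sample_interval: int = 250


def replicate_seed(seed: int, index: int) -> int:
    """Deterministic child seed below 2**31 for replicate ``index``."""
    ss = np.random.SeedSequence(entropy=int(seed) % (2**31), spawn_key=(1, index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_sweep(spec: SweepSpec, keep_runs: bool = False) -> pd.DataFrame:
    """Run every grid cell and summarize final largest-tower properties.

    Returns one row per cell with the mean, min and max over replicates
    of the final largest tower's agent count, height and aspect ratio
    (plus per-replicate rows in ``attrs['replicates']`` if requested).
    """
    rows = []
    rep_rows = []
    idx = 0
    for Pu, knl, c, N in itertools.product(spec.Pu, spec.knl, spec.c, spec.N):
        vals = []
        for r in range(spec.replicates):
            params = SimulationParams(
                L=spec.L,
                N=N,
                Pu=Pu,
                knl=knl,
                Psl=spec.Psl,
                c=c,
                steps=spec.steps,
                seed=replicate_seed(spec.seed, idx),
                sample_interval=spec.sample_interval,
            )
            idx += 1
            res = run(params)
            s = res.final_largest
            vals.append((s.n_agents, s.height, s.aspect_ratio))
            rep_rows.append(
                dict(
                    Pu=Pu, knl=knl, c=c, N=N, rho=N / spec.L**2, replicate=r,
                    n_agents=s.n_agents, height=s.height,
                    aspect_ratio=s.aspect_ratio, steady=res.is_steady(),
                )
            )
        arr = np.asarray(vals, dtype=float)
        rows.append(
            dict(
                Pu=Pu, knl=knl, c=c, N=N, rho=N / spec.L**2,
                n_agents_mean=arr[:, 0].mean(),
                n_agents_min=arr[:, 0].min(),
                n_agents_max=arr[:, 0].max(),
                height_mean=arr[:, 1].mean(),
                height_min=arr[:, 1].min(),
                height_max=arr[:, 1].max(),
                aspect_ratio_mean=arr[:, 2].mean(),
                aspect_ratio_min=arr[:, 2].min(),
                aspect_ratio_max=arr[:, 2].max(),
            )
        )
    df = pd.DataFrame(rows)
    if keep_runs:
        df.attrs["replicates"] = pd.DataFrame(rep_rows)
    return df


def critical_attraction(
    c_grid, mean_sizes, threshold: float = ONSET_THRESHOLD
):
    """Onset of the aggregation phase transition along an attraction grid.

    Returns the smallest grid value of ``c`` whose mean largest-tower
    size reaches ``threshold`` agents, or ``None`` if no grid point
    does.  The grid must be strictly increasing.
    """
    c_grid = np.asarray(c_grid, dtype=float)
    mean_sizes = np.asarray(mean_sizes, dtype=float)
    if c_grid.size != mean_sizes.size:
        raise ValueError("c grid and sizes differ in length")
    if np.any(np.diff(c_grid) <= 0):
        raise ValueError("c grid must be strictly increasing")
    hits = np.flatnonzero(mean_sizes >= threshold)
    return float(c_grid[hits[0]]) if hits.size else None


# ----------------------------------------------------------------------
# tower tracking


@dataclass
class TowerTrajectory:
    """Center-of-area track of one tower through sampled frames.

    Positions are unwrapped: each frame's center is the previous one
    plus the minimal-image displacement, so seam crossings accumulate
    instead of jumping by ``L``.
    """

    track_id: int
    times: np.ndarray  # sample times, strictly increasing
    positions: np.ndarray  # (k, 2) unwrapped centers, pixels

    @property
    def T(self) -> int:
        """Trajectory length in steps."""
        return int(self.times[-1] - self.times[0])

    @property
    def stride(self) -> int:
        return int(self.times[1] - self.times[0]) if self.times.size > 1 else 0


def _frame_regions(labels: np.ndarray):
    """label -> (pixel set, area, center array) for one label image."""
    out = {}
    for lab in np.unique(labels):
        if lab == 0:
            continue
        xs, ys = np.nonzero(labels == lab)
        out[int(lab)] = (
            set(zip(xs.tolist(), ys.tolist())),
            xs.size,
            periodic_centroid(np.column_stack([xs, ys]), labels.shape[0]),
        )
    return out


def track_towers(
    frames: list,
    times: np.ndarray | None = None,
    L: int | None = None,
    overlap_fraction: float = 0.3,
    center_radius: float = 5.0,
    stride: int = SAMPLE_STRIDE,
) -> list:
    """Associate labeled towers across sampled frames into trajectories.

    ``frames`` is a sequence of label images (e.g. from
    :func:`anttower.metrics.label_towers` applied to sampled height
    maps).  Towers are matched frame-to-frame when their footprints
    overlap by more than ``overlap_fraction`` of the smaller footprint;
    leftover towers match to the nearest unmatched center within
    ``center_radius`` pixels (periodic distance).  Any merge or split
    ends the tracks involved and opens fresh ones, so a trajectory
    never mixes towers across a merge.  Returns the list of
    :class:`TowerTrajectory`, unwrapped across the periodic seam.
    """
    if times is None:
        times = np.arange(len(frames)) * stride
    times = np.asarray(times)
    if L is None and frames:
        L = frames[0].shape[0]

    tracks: list[TowerTrajectory] = []
    open_tracks: dict[int, dict] = {}  # current frame label -> track data
    next_id = 0

    prev_regions: dict = {}
    for fi, labels in enumerate(frames):
        regions = _frame_regions(labels)
        assigned: dict[int, int] = {}  # cur label -> prev label
        if prev_regions and regions:
            # overlap edges
            edges = []
            for pl, (ppix, parea, _pc) in prev_regions.items():
                for cl, (cpix, carea, _cc) in regions.items():
                    ov = len(ppix & cpix)
                    if ov and ov / min(parea, carea) > overlap_fraction:
                        edges.append((pl, cl))
            pdeg: dict[int, int] = {}
            cdeg: dict[int, int] = {}
            for pl, cl in edges:
                pdeg[pl] = pdeg.get(pl, 0) + 1
                cdeg[cl] = cdeg.get(cl, 0) + 1
            for pl, cl in edges:
                # only clean one-to-one overlaps continue a track
                if pdeg[pl] == 1 and cdeg[cl] == 1:
                    assigned[cl] = pl
            # center-distance fallback for still-unmatched towers
            free_prev = [
                pl
                for pl in prev_regions
                if pl not in assigned.values() and pdeg.get(pl, 0) == 0
            ]
            for cl, (_cpix, _carea, cc) in regions.items():
                if cl in assigned or cdeg.get(cl, 0) > 0:
                    continue
                best, best_d = None, center_radius
                for pl in free_prev:
                    d = periodic_distance(prev_regions[pl][2], cc, L)
                    if d <= best_d:
                        best, best_d = pl, d
                if best is not None:
                    assigned[cl] = best
                    free_prev.remove(best)

        new_open: dict[int, dict] = {}
        for cl, (_pix, _area, center) in regions.items():
            pl = assigned.get(cl)
            if pl is not None and pl in open_tracks:
                data = open_tracks.pop(pl)
                d = np.asarray(
                    toroidal_offset(data["last_wrapped"], center, L), dtype=float
                )
                data["pos"].append(data["pos"][-1] + d)
                data["times"].append(times[fi])
                data["last_wrapped"] = center
                new_open[cl] = data
            else:
                new_open[cl] = dict(
                    id=next_id,
                    times=[times[fi]],
                    pos=[np.asarray(center, dtype=float)],
                    last_wrapped=center,
                )
                next_id += 1
        # tracks with no continuation close now
        for data in open_tracks.values():
            tracks.append(
                TowerTrajectory(
                    data["id"], np.asarray(data["times"]), np.asarray(data["pos"])
                )
            )
        open_tracks = new_open
        prev_regions = regions

    for data in open_tracks.values():
        tracks.append(
            TowerTrajectory(
                data["id"], np.asarray(data["times"]), np.asarray(data["pos"])
            )
        )
    tracks.sort(key=lambda tr: tr.track_id)
    return tracks


# ----------------------------------------------------------------------
# MSD and diffusion


def msd(traj: TowerTrajectory, lag: int) -> float:
    """Mean squared displacement of a trajectory at one time lag.

    Sliding-window average of ``|x(t0 + lag) - x(t0)|^2`` over every
    valid window start; ``lag`` must be a multiple of the sampling
    stride and smaller than the trajectory length.  ``msd(traj, 0)`` is
    exactly 0.
    """
    if lag == 0:
        return 0.0
    stride = traj.stride
    if stride <= 0 or traj.T < 1:
        raise ValueError("trajectory too short for a nonzero lag")
    if lag % stride != 0:
        raise ValueError(f"lag {lag} is not a multiple of the stride {stride}")
    k = lag // stride
    if k >= traj.times.size:
        raise ValueError(f"lag {lag} >= trajectory length {traj.T}")
    d = traj.positions[k:] - traj.positions[:-k]
    return float(np.mean(np.sum(d * d, axis=1)))


@dataclass(frozen=True)
class DiffusionEstimate:
    """Linear MSD fit of one trajectory: ``MSD = slope * t + intercept``."""

    D: float  # pixels^2 per step, = slope / 2
    slope: float
    intercept: float
    lags: np.ndarray


def diffusion_coefficient(
    traj: TowerTrajectory,
    max_lag: int = MSD_MAX_LAG,
    fit_window: int = FIT_WINDOW,
) -> DiffusionEstimate:
    """Diffusion coefficient of one tower trajectory.

    The trajectory is truncated to its first ``fit_window`` steps, the
    MSD evaluated at lags ``0, stride, ..., max_lag``, and an unweighted
    least-squares line fitted through them (the (0, 0) point included);
    ``D`` is half the slope.  Raises if fewer than two lags fit.
    """
    stride = traj.stride
    if stride <= 0:
        raise ValueError("trajectory has fewer than two samples")
    keep = traj.times - traj.times[0] <= fit_window
    sub = TowerTrajectory(traj.track_id, traj.times[keep], traj.positions[keep])
    lags = np.arange(0, max_lag + 1, stride)
    lags = lags[lags < sub.T + 1]
    lags = lags[(lags // stride) < sub.times.size]
    if lags.size < 2:
        raise ValueError("trajectory too short: fewer than two usable lags")
    values = np.array([msd(sub, int(t)) for t in lags])
    slope, intercept = np.polyfit(lags.astype(float), values, 1)
    return DiffusionEstimate(D=float(slope) / 2.0, slope=float(slope),
                             intercept=float(intercept), lags=lags)


def mean_diffusion(trajectories: list, min_samples: int = 2) -> tuple:
    """Unweighted mean ``D`` over all fittable trajectories.

    Tracks too short for two lags are excluded.  Returns
    ``(mean_D, n_used, estimates)``; ``mean_D`` is NaN when no track
    qualifies.
    """
    estimates = []
    for tr in trajectories:
        if tr.times.size < min_samples:
            continue
        try:
            estimates.append(diffusion_coefficient(tr))
        except ValueError:
            continue
    if not estimates:
        return float("nan"), 0, []
    return float(np.mean([e.D for e in estimates])), len(estimates), estimates


def run_diffusion_analysis(params: SimulationParams) -> tuple:
    """Run one simulation and estimate tower diffusion from its snapshots.

    Convenience pipeline: simulate with height-map snapshots every
    ``sample_interval`` steps, label each frame, track towers, and
    average the per-track diffusion coefficients.  Returns
    ``(mean_D, tracks, estimates)``.
    """
    res = run(params, record_snapshots=True)
    frames = [metrics.label_towers(hm) for _t, hm, _s in res.snapshots]
    times = np.array([t for t, _hm, _s in res.snapshots])
    tracks = track_towers(frames, times=times, L=params.L,
                          stride=params.sample_interval)
    mean_D, _n, estimates = mean_diffusion(tracks)
    return mean_D, tracks, estimates
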