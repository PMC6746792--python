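"""Synthetic bead-track generators with known ground truth.

Each measurement mode of the pipeline has a generator producing a
:class:`~dorsaflow.trajectories.TrackTable` with the statistical structure
that mode assumes, plus a truth table of the generating parameters:

- ``traction``: beads crawling against the flow at constant log-normally
  distributed speeds (10 s frames, 5 min), with i.i.d. Gaussian localisation
  noise on every frame;
- ``creep``: four-element viscoelastic creep under constant force followed
  by superposed recovery after flow-off (0.5 s frames, 3 min), per-cell
  parameters log-normally scattered around (G_0, G_1, µ'_0, µ'_1) =
  (500, 200, 550, 50) so the mean instantaneous stiffness E_0+E_1 sits near
  2 kPa at ν = 0.4;
- ``ramp``: beads detaching at the first ramp step whose force exceeds a
  per-bead threshold drawn from a log-normal mixture (a sharp low-force
  component, or a bimodal mixture with a high-force tail beyond the ramp).

A minimal image front-end (Gaussian spots on a constant background with
Poisson shot noise, plus a nearest-neighbour detector/linker) exercises the
tracking entry point on synthetic stacks.  All generators are bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .hydro_calibration import HydroContext, terminal_drag_force
from .traction import InterfaceModel, interfacial_drag
from .trajectories import TrackTable, Trajectory
from .viscoelasticity import geometry_prefactor, kv4_compliance

logger = logging.getLogger(__name__)

_MODE_DEFAULTS = {
    # mode: (frame_interval s, duration s, flow_rate µl/min)
    "traction": (10.0, 300.0, 10.0),
    "creep": (0.5, 180.0, 1000.0),
    "ramp": (1.0, 210.0, None),
}

#: default central creep parameters: G_0, G_1 (Pa), µ'_0, µ'_1 (Pa·s)
CREEP_CENTRAL = (500.0, 200.0, 550.0, 50.0)


@dataclass
class SyntheticScenario:
    """Study conditions for one synthetic experiment.

    Defaults follow the imaging protocols of the measurement modes: 10 s
    frames for 5 min (traction), 0.5 s frames for 3 min (creep), 1 s frames
    over the 7-step ramp (ramp).  ``noise_sigma`` is the localisation noise
    in metres (50 nm ≈ 0.1 px of sub-pixel tracking at 10X).
    """

    mode: str
    n_particles: int = 50
    noise_sigma: float = 5e-8  # m, per-frame i.i.d. Gaussian on each coordinate
    frame_interval: float | None = None  # s; mode default when None
    duration: float | None = None  # s; mode default when None
    seed: int = 0
    flow_rate: float | None = None  # µl/min; mode default when None
    applied_force: float | None = None  # N; computed from flow_rate when None
    # traction mode
    speed_median: float = 2e-8  # m/s
    speed_sigma_log: float = 0.3
    # creep mode
    flow_on: float = 10.0  # s
    flow_off: float = 100.0  # s
    creep_params: tuple = CREEP_CENTRAL
    param_sigma_log: float = 0.3
    # ramp mode: list of (weight, median N multiplier context, sigma_log) built
    # by preset when None; see gen_ramp_tracks
    threshold_preset: str = "integrin"

    def __post_init__(self) -> None:
        if self.mode not in _MODE_DEFAULTS:
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.n_particles < 1:
            raise ConfigurationError("n_particles must be >= 1")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise sigma must be >= 0")
        fi, dur, q = _MODE_DEFAULTS[self.mode]
        if self.frame_interval is None:
            self.frame_interval = fi
        if self.duration is None:
            self.duration = dur
        if self.flow_rate is None:
            self.flow_rate = q


def _resolve_force(scenario: SyntheticScenario, ctx: HydroContext) -> float:
    if scenario.applied_force is not None:
        return scenario.applied_force
    return terminal_drag_force(ctx.reference_height, scenario.flow_rate, ctx)


def _times(scenario: SyntheticScenario) -> np.ndarray:
    n = int(round(scenario.duration / scenario.frame_interval)) + 1
    return np.arange(n) * scenario.frame_interval


def _start_positions(rng: np.random.Generator, n: int) -> np.ndarray:
    # spread through a 500 µm field of view, away from the edges
    return rng.uniform(30.0, 470.0, size=(n, 2))


def gen_traction_tracks(
    scenario: SyntheticScenario,
    ctx: HydroContext | None = None,
    iface: InterfaceModel | None = None,
) -> tuple[TrackTable, pd.DataFrame]:
    """Beads moving against the flow at constant per-bead speeds.

    Speeds are log-normal (median ``speed_median``, log-sd
    ``speed_sigma_log``); the truth table carries each bead's speed and the
    implied traction force F_C = F_A + 6πa·µ_c·u·f(θ).
    """
    if scenario.mode != "traction":
        raise ConfigurationError("scenario mode must be 'traction'")
    ctx = ctx or HydroContext()
    iface = iface or InterfaceModel()
    rng = np.random.default_rng(scenario.seed)
    f_a = _resolve_force(scenario, ctx)
    t = _times(scenario)
    sigma_um = scenario.noise_sigma * 1e6
    starts = _start_positions(rng, scenario.n_particles)
    speeds = scenario.speed_median * rng.lognormal(
        0.0, scenario.speed_sigma_log, scenario.n_particles
    )
    axis = np.array([1.0, 0.0])

    trajectories, rows, wall = [], [], {}
    for i in range(scenario.n_particles):
        drift = -speeds[i] * 1e6 * t  # µm, against flow
        noise = rng.normal(0.0, sigma_um, size=(t.size, 2)) if sigma_um else 0.0
        xy = starts[i] + drift[:, None] * axis
        if sigma_um:
            xy = xy + noise
        trajectories.append(
            Trajectory(track_id=i, times=t, x=xy[:, 0], y=xy[:, 1], flow_axis=axis)
        )
        wall[i] = 500.0
        rows.append(
            {
                "track": i,
                "u_true_m_per_s": speeds[i],
                "F_A_N": f_a,
                "F_C_true_N": f_a + interfacial_drag(speeds[i], iface, ctx.particle),
            }
        )
    table = TrackTable(
        trajectories=trajectories,
        frame_interval=scenario.frame_interval,
        wall_distance=wall,
    )
    return table, pd.DataFrame(rows)


def gen_creep_tracks(
    scenario: SyntheticScenario, ctx: HydroContext | None = None
) -> tuple[TrackTable, pd.DataFrame]:
    """Creep-and-recovery bead displacements from the four-element model.

    X(t) = (F_A/(6πaC))·J(t − t_on) during creep, and the superposition
    (F_A/(6πaC))·[J(t − t_on) − J(t − t_off)] after flow-off, so the
    recovery continues the creep endpoint (up to the instantaneous elastic
    recoil).  Per-cell parameters are log-normal around ``creep_params``.
    """
    if scenario.mode != "creep":
        raise ConfigurationError("scenario mode must be 'creep'")
    ctx = ctx or HydroContext()
    rng = np.random.default_rng(scenario.seed)
    f_a = _resolve_force(scenario, ctx)
    pref_um = f_a / geometry_prefactor(ctx) * 1e6
    t = _times(scenario)
    if not (t[0] <= scenario.flow_on < scenario.flow_off <= t[-1]):
        raise ConfigurationError("flow window must lie inside the acquisition")
    sigma_um = scenario.noise_sigma * 1e6
    starts = _start_positions(rng, scenario.n_particles)
    central = np.asarray(scenario.creep_params, dtype=float)
    axis = np.array([1.0, 0.0])

    trajectories, rows, wall = [], [], {}
    for i in range(scenario.n_particles):
        params = central * rng.lognormal(0.0, scenario.param_sigma_log, 4)
        g0, g1, mu0, mu1 = params
        disp = np.zeros_like(t)
        creep = (t > scenario.flow_on) & (t <= scenario.flow_off)
        disp[creep] = pref_um * kv4_compliance(
            t[creep] - scenario.flow_on, g0, g1, mu0, mu1
        )
        rec = t > scenario.flow_off
        disp[rec] = pref_um * (
            kv4_compliance(t[rec] - scenario.flow_on, g0, g1, mu0, mu1)
            - kv4_compliance(t[rec] - scenario.flow_off, g0, g1, mu0, mu1)
        )
        xy = starts[i] + disp[:, None] * axis
        if sigma_um:
            xy = xy + rng.normal(0.0, sigma_um, size=(t.size, 2))
        trajectories.append(
            Trajectory(track_id=i, times=t, x=xy[:, 0], y=xy[:, 1], flow_axis=axis)
        )
        wall[i] = 500.0
        rows.append(
            {
                "track": i,
                "G0_Pa": g0,
                "G1_Pa": g1,
                "mu0_shear_Pa_s": mu0,
                "mu1_shear_Pa_s": mu1,
                "F_A_N": f_a,
                "E0_plus_E1_Pa": 2.0 * (g0 + g1) * 1.4,  # ν = 0.4
            }
        )
    table = TrackTable(
        trajectories=trajectories,
        frame_interval=scenario.frame_interval,
        wall_distance=wall,
    )
    return table, pd.DataFrame(rows)


def threshold_mixture(preset: str, forces: np.ndarray) -> list[tuple]:
    """Mixture components (weight, median N, sigma_log) for rupture thresholds.

    ``"cd80"``: one sharp component below the first step force, so every
    bond fails at step 1.  ``"integrin"``: 27 % of the mass between the
    step-1 and step-2 forces and 73 % far above the maximal ramp force, so
    the survival curve drops once at step 2 and then plateaus.
    """
    if preset == "cd80":
        return [(1.0, 0.75 * forces[0], 0.02)]
    if preset == "integrin":
        return [
            (0.27, float(np.sqrt(forces[0] * forces[1])), 0.03),
            (0.73, 3.0 * forces[-1], 0.05),
        ]
    raise ConfigurationError(f"unknown threshold preset {preset!r}")


def gen_ramp_tracks(
    scenario: SyntheticScenario,
    forces: np.ndarray,
    components: list[tuple] | None = None,
) -> tuple[TrackTable, pd.DataFrame]:
    """Bead tracks under the step ramp with mixture-distributed thresholds.

    ``forces`` is the per-step applied force schedule (N).  A bead with
    threshold T detaches (its track ends) partway through the first step
    whose force exceeds T; attached beads show only localisation jitter,
    far below the 5 µm detachment rule.  The truth table stores T and the
    0-based detachment step (−1 when the bead survives the ramp).
    """
    if scenario.mode != "ramp":
        raise ConfigurationError("scenario mode must be 'ramp'")
    forces = np.asarray(forces, dtype=float)
    rng = np.random.default_rng(scenario.seed)
    if components is None:
        components = threshold_mixture(scenario.threshold_preset, forces)
    weights = np.array([c[0] for c in components])
    weights = weights / weights.sum()
    t = _times(scenario)
    step = scenario.duration / forces.size
    sigma_um = scenario.noise_sigma * 1e6
    starts = _start_positions(rng, scenario.n_particles)
    axis = np.array([1.0, 0.0])

    comp_idx = rng.choice(len(components), size=scenario.n_particles, p=weights)
    thresholds = np.array(
        [
            components[c][1] * rng.lognormal(0.0, components[c][2])
            for c in comp_idx
        ]
    )

    trajectories, rows, wall = [], [], {}
    for i in range(scenario.n_particles):
        exceed = np.nonzero(forces > thresholds[i])[0]
        detach_step = int(exceed[0]) if exceed.size else -1
        if detach_step >= 0:
            t_end = (detach_step + 0.4) * step
            keep = t <= t_end
        else:
            keep = np.ones_like(t, dtype=bool)
        tt = t[keep]
        xy = np.tile(starts[i], (tt.size, 1))
        if sigma_um:
            xy = xy + rng.normal(0.0, sigma_um, size=(tt.size, 2))
        trajectories.append(
            Trajectory(track_id=i, times=tt, x=xy[:, 0], y=xy[:, 1], flow_axis=axis)
        )
        wall[i] = 500.0
        rows.append(
            {"track": i, "threshold_N": thresholds[i], "detach_step": detach_step}
        )
    table = TrackTable(
        trajectories=trajectories,
        frame_interval=scenario.frame_interval,
        wall_distance=wall,
    )
    return table, pd.DataFrame(rows)


def gen_image_stack(
    table: TrackTable,
    shape: tuple[int, int] = (128, 128),
    pixel_size: float = 1.0,
    psf_sigma: float = 1.5,
    background: float = 100.0,
    amplitude: float = 4000.0,
    poisson_noise: bool = True,
    seed: int = 0,
) -> np.ndarray:
    """Render a track table as a 16-bit image stack (T, rows, cols).

    Gaussian spots of width ``psf_sigma`` px on a constant background with
    optional Poisson shot noise.  ``pixel_size`` (µm/px) maps positions to
    pixels; out-of-frame positions are clipped with a warning.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    all_times = np.unique(np.concatenate([traj.times for traj in table]))
    frames = np.rint(all_times / table.frame_interval).astype(int)
    n_frames = frames.max() + 1
    stack = np.full((n_frames, n_rows, n_cols), background, dtype=float)
    rr, cc = np.mgrid[0:n_rows, 0:n_cols]

    clipped = 0
    for traj in table:
        f = np.rint(traj.times / table.frame_interval).astype(int)
        col = traj.x / pixel_size
        row = traj.y / pixel_size
        out = (col < 0) | (col > n_cols - 1) | (row < 0) | (row > n_rows - 1)
        clipped += int(out.sum())
        col = np.clip(col, 0, n_cols - 1)
        row = np.clip(row, 0, n_rows - 1)
        for k in range(f.size):
            stack[f[k]] += amplitude * np.exp(
                -((rr - row[k]) ** 2 + (cc - col[k]) ** 2) / (2.0 * psf_sigma**2)
            )
    if clipped:
        warnings.warn(f"{clipped} position(s) outside the frame were clipped")
    if poisson_noise:
        stack = rng.poisson(stack).astype(float)
    return np.clip(stack, 0, 65535).astype(np.uint16)


def detect_and_link(
    stack: np.ndarray,
    threshold: float,
    max_disp: float,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    flow_axis=(1.0, 0.0),
) -> TrackTable:
    """Minimal spot detector and greedy nearest-neighbour linker.

    Spots are intensity-weighted centroids of above-threshold connected
    components; links are accepted greedily by ascending distance within the
    ``max_disp`` gate (px).  Unlinked spots start new tracks; tracks are not
    resumed after a missed frame (no gap closing).
    """
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (T, rows, cols) with >= 2 frames")
    detections = []  # per frame: array (n, 2) of (row, col)
    for frame in stack:
        img = frame.astype(float) - threshold
        mask = img > 0
        labels, n = ndimage.label(mask)
        if n == 0:
            detections.append(np.empty((0, 2)))
            continue
        coms = ndimage.center_of_mass(img * mask, labels, range(1, n + 1))
        detections.append(np.asarray(coms, dtype=float))
    if all(d.shape[0] == 0 for d in detections):
        warnings.warn("no spots detected in any frame")
        return TrackTable(
            trajectories=[], frame_interval=frame_interval, pixel_size=pixel_size
        )

    next_id = 0
    active: dict[int, dict] = {}  # id -> {"pos": (r, c), "frames": [...], "rc": [...]}
    finished: list[dict] = []
    for f_idx, spots in enumerate(detections):
        assigned_spots = set()
        assigned_tracks = set()
        if active and spots.shape[0]:
            pairs = []
            for tid, tr in active.items():
                d = np.hypot(
                    spots[:, 0] - tr["pos"][0], spots[:, 1] - tr["pos"][1]
                )
                for s_idx in range(spots.shape[0]):
                    if d[s_idx] <= max_disp:
                        pairs.append((d[s_idx], tid, s_idx))
            for _, tid, s_idx in sorted(pairs, key=lambda p: p[0]):
                if tid in assigned_tracks or s_idx in assigned_spots:
                    continue
                tr = active[tid]
                tr["pos"] = spots[s_idx]
                tr["frames"].append(f_idx)
                tr["rc"].append(spots[s_idx])
                assigned_tracks.add(tid)
                assigned_spots.add(s_idx)
        # retire unmatched tracks
        for tid in [tid for tid in active if tid not in assigned_tracks]:
            finished.append(active.pop(tid))
        # start new tracks for unmatched spots
        for s_idx in range(spots.shape[0]):
            if s_idx in assigned_spots:
                continue
            active[next_id] = {
                "pos": spots[s_idx],
                "frames": [f_idx],
                "rc": [spots[s_idx]],
            }
            next_id += 1
    finished.extend(active.values())

    axis = np.asarray(flow_axis, dtype=float)
    trajectories = []
    tid = 0
    for tr in sorted(finished, key=lambda tr: (tr["frames"][0], tr["rc"][0][1])):
        if len(tr["frames"]) < 2:
            continue
        rc = np.asarray(tr["rc"])
        trajectories.append(
            Trajectory(
                track_id=tid,
                times=np.asarray(tr["frames"], dtype=float) * frame_interval,
                x=rc[:, 1] * pixel_size,
                y=rc[:, 0] * pixel_size,
                flow_axis=axis,
            )
        )
        tid += 1
    return TrackTable(
        trajectories=trajectories, frame_interval=frame_interval, pixel_size=pixel_size
    )
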