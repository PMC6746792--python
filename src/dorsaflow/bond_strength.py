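"""Bond rupture forces from particle attachment counts under a flow ramp.

Ligand-coated beads bound to cell-surface receptors are subjected to a
step-wise increasing flow (default 200 → 1400 µl/min in 200 µl/min steps of
30 s).  Beads detach once the applied force exceeds the strength of the
multivalent receptor–ligand bond cluster holding them; the per-step count of
still-attached beads yields a survival curve over force, and the rupture
force is reported as the step force with the largest fractional single-step
loss.  This is a bond-cluster strength at step resolution (a lower bound on
the true threshold within a 30 s step), not a single-molecule force.

Counting convention: ``counts[0]`` is the number of tracked beads present at
ramp start; ``counts[k]`` (k >= 1) is the number still attached through the
end of step k.  The drop into ``counts[k]`` is attributed to the force of
step k, i.e. ``forces[k-1]`` in 0-based indexing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, TrackDataError
from .hydro_calibration import applied_force
from .trajectories import TrackTable, project_displacement

#: within-step along-flow displacement above which a bead counts as detached, µm
DEFAULT_DETACH_THRESHOLD_UM = 5.0

#: default ramp flow rates, µl/min
DEFAULT_RAMP_RATES = tuple(range(200, 1401, 200))


@dataclass(frozen=True)
class RampProtocol:
    """Step-wise flow ramp: strictly increasing rates, fixed step duration."""

    rates: tuple = DEFAULT_RAMP_RATES  # µl/min
    step_duration: float = 30.0  # s
    start_time: float = 0.0  # s, ramp start in track time

    def __post_init__(self) -> None:
        rates = tuple(self.rates)
        object.__setattr__(self, "rates", rates)
        if len(rates) < 1 or any(b <= a for a, b in zip(rates, rates[1:])):
            raise ConfigurationError("ramp rates must be strictly increasing")
        if self.step_duration <= 0:
            raise ConfigurationError("step duration must be > 0")

    @property
    def n_steps(self) -> int:
        return len(self.rates)

    @property
    def total_duration(self) -> float:
        return self.n_steps * self.step_duration

    def step_window(self, k: int) -> tuple[float, float]:
        """Time window [start, end) of step ``k`` (0-based)."""
        t0 = self.start_time + k * self.step_duration
        return t0, t0 + self.step_duration


@dataclass(frozen=True)
class RuptureResult:
    """Survival analysis of a ramp experiment.

    ``rupture_force`` is None (with flag ``"no_detachment"``) when no bead
    ever detaches.  ``fraction_detached[j]`` is the fraction of survivors
    lost to the force of step j+1, aligned with ``forces[j]`` (last entry
    unobservable, reported 0).
    """

    counts: np.ndarray
    survival: np.ndarray
    forces: np.ndarray
    rupture_force: float | None
    rupture_step: int | None  # 0-based index into forces
    fraction_detached: np.ndarray
    initial_count: int
    flag: str | None = None


def step_force_schedule(
    protocol: RampProtocol,
    calibrations: dict | list,
    x: float,
) -> np.ndarray:
    """Applied force (N) at wall distance ``x`` for each ramp step.

    ``calibrations`` is a mapping flow rate → :class:`ForceCalibration` (or a
    list matched to the protocol rates); one calibration per step rate is
    required.
    """
    if isinstance(calibrations, dict):
        cal_map = calibrations
    else:
        cal_map = {cal.flow_rate: cal for cal in calibrations}
    forces = []
    for rate in protocol.rates:
        if rate not in cal_map:
            raise ConfigurationError(f"no calibration for flow rate {rate} µl/min")
        forces.append(applied_force(x, cal_map[rate]))
    forces = np.array(forces)
    if np.any(np.diff(forces) <= 0):
        raise ConfigurationError("step forces are not strictly increasing")
    return forces


def count_attached(
    table: TrackTable,
    protocol: RampProtocol,
    detach_threshold: float = DEFAULT_DETACH_THRESHOLD_UM,
) -> np.ndarray:
    """Per-step attached counts under the ramp.

    A bead is attached through step k if its track covers the whole step
    window and its along-flow displacement within the window stays below
    ``detach_threshold`` (µm).  Detachment is absorbing: once a bead fails
    either test it is not counted at any later step.  Entry 0 is the number
    of tracks present at ramp start.
    """
    if len(table) == 0:
        raise TrackDataError("empty track table")
    eps = 1e-9
    counts = np.zeros(protocol.n_steps, dtype=int)
    for traj in table:
        if traj.times[0] > protocol.start_time + eps:
            continue  # appeared after ramp start: not in the initial cohort
        counts[0] += 1
        for k in range(1, protocol.n_steps):
            t0, t1 = protocol.step_window(k - 1)
            if traj.times[-1] < t1 - eps:
                break  # track ends inside the step: detached
            series = project_displacement(traj, t0)
            window = series.values[series.times <= t1 + eps]
            if window.size and (window.max() - window.min()) >= detach_threshold:
                break
            counts[k] += 1
    return counts


def rupture_force(counts, forces) -> RuptureResult:
    """Survival curve and rupture force from per-step counts.

    Survival S(k) = counts[k]/counts[0]; the rupture force is the step force
    with the maximum fractional single-step drop (earliest step wins ties).
    Any increase in counts raises an error: re-attachment is not modelled.
    """
    counts = np.asarray(counts, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if counts.size != forces.size:
        raise ValueError("counts and forces must have equal length")
    if counts.size < 2:
        raise ValueError("need at least two steps")
    if counts[0] <= 0:
        raise TrackDataError("zero particles attached at ramp start")
    if np.any(np.diff(counts) > 0):
        raise TrackDataError("attached counts increased: re-attachment not modelled")
    survival = counts / counts[0]

    frac = np.zeros(forces.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        drops = np.where(counts[:-1] > 0, (counts[:-1] - counts[1:]) / counts[:-1], 0.0)
    frac[: drops.size] = drops  # frac[j] is the loss under forces[j]
    if np.all(drops == 0):
        return RuptureResult(
            counts=counts.astype(int),
            survival=survival,
            forces=forces,
            rupture_force=None,
            rupture_step=None,
            fraction_detached=frac,
            initial_count=int(counts[0]),
            flag="no_detachment",
        )
    step = int(np.argmax(drops))  # argmax takes the earliest maximal drop
    return RuptureResult(
        counts=counts.astype(int),
        survival=survival,
        forces=forces,
        rupture_force=float(forces[step]),
        rupture_step=step,
        fraction_detached=frac,
        initial_count=int(counts[0]),
    )


def analyze_ramp(
    table: TrackTable,
    protocol: RampProtocol,
    calibrations: dict | list,
    x: float,
    detach_threshold: float = DEFAULT_DETACH_THRESHOLD_UM,
) -> RuptureResult:
    """Full ramp analysis: force schedule, attached counts, rupture force."""
    forces = step_force_schedule(protocol, calibrations, x)
    counts = count_attached(table, protocol, detach_threshold)
    return rupture_force(counts, forces)
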