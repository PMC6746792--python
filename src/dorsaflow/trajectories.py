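"""Particle-track data model, CSV I/O and kinematic reductions.

Tracks are stored in image coordinates (x, y in micrometres, origin top-left)
together with the flow direction as a unit vector, so that every downstream
force estimate reduces to a scalar displacement along the flow axis.  Two CSV
dialects are understood: the TrackMate spot export (``TRACK_ID``, ``FRAME``,
``POSITION_X``, ``POSITION_Y``) and a generic ``track,frame,x,y`` layout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, QCError, TrackDataError, TrackFormatError

logger = logging.getLogger(__name__)

#: column maps for the supported CSV dialects
_TRACKMATE_COLUMNS = {
    "track": "TRACK_ID",
    "frame": "FRAME",
    "x": "POSITION_X",
    "y": "POSITION_Y",
}
_GENERIC_COLUMNS = {"track": "track", "frame": "frame", "x": "x", "y": "y"}
_WALL_DISTANCE_COLUMNS = ("wall_distance", "WALL_DISTANCE")

#: minimum number of samples for a velocity fit
MIN_VELOCITY_SAMPLES = 5
#: velocity fits with r² below this are flagged (not dropped)
MIN_VELOCITY_R2 = 0.8
#: default side-wall exclusion distance, µm
DEFAULT_WALL_DISTANCE_UM = 200.0


@dataclass(frozen=True)
class Trajectory:
    """One particle's time-ordered positions.

    Parameters
    ----------
    track_id:
        Identifier carried through to every per-track result.
    times:
        Sample times in seconds, strictly increasing, at least two samples.
    x, y:
        Positions in micrometres, image coordinates.
    flow_axis:
        Unit 2-vector giving the direction of flow in image coordinates.
    """

    track_id: object
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    flow_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        axis = np.asarray(self.flow_axis, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if times.ndim != 1 or times.size < 2:
            raise TrackDataError(
                f"track {self.track_id!r}: need >= 2 samples, got {times.size}"
            )
        if x.shape != times.shape or y.shape != times.shape:
            raise TrackDataError(f"track {self.track_id!r}: shape mismatch")
        if not np.all(np.diff(times) > 0):
            raise TrackDataError(
                f"track {self.track_id!r}: times must be strictly increasing"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise TrackDataError(f"track {self.track_id!r}: non-finite positions")
        norm = float(np.hypot(axis[0], axis[1]))
        if axis.shape != (2,) or norm == 0 or not np.isfinite(norm):
            raise TrackDataError("flow_axis must be a finite non-zero 2-vector")
        object.__setattr__(self, "flow_axis", axis / norm)

    @property
    def n_samples(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class TrackTable:
    """A collection of trajectories sharing acquisition metadata.

    ``wall_distance`` maps track_id to the distance (µm) of the track from the
    nearest channel side wall, when known; it drives :func:`filter_side_wall`.
    """

    trajectories: list[Trajectory]
    frame_interval: float
    pixel_size: float = 1.0
    wall_distance: dict | None = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def get(self, track_id) -> Trajectory:
        for traj in self.trajectories:
            if traj.track_id == track_id:
                return traj
        raise KeyError(track_id)

    @property
    def track_ids(self) -> list:
        return [t.track_id for t in self.trajectories]


@dataclass(frozen=True)
class DisplacementSeries:
    """Scalar displacement along the flow axis, µm versus s."""

    times: np.ndarray
    values: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class VelocityEstimate:
    """OLS velocity of a displacement series.

    ``speed`` is the absolute slope in m/s; ``sign`` is +1 along flow, -1
    against; ``flag`` is ``None``, ``"degenerate"`` (constant series) or
    ``"low_r2"`` (r² < 0.8).
    """

    speed: float
    sign: int
    r_squared: float
    flag: str | None = None


def _resolve_dialect(columns: Sequence[str]) -> Mapping[str, str]:
    cols = set(columns)
    if _TRACKMATE_COLUMNS["track"] in cols:
        mapping = _TRACKMATE_COLUMNS
    else:
        mapping = _GENERIC_COLUMNS
    missing = [c for c in mapping.values() if c not in cols]
    if missing:
        raise TrackFormatError(
            f"missing required column(s): {', '.join(missing)} (found {sorted(cols)})"
        )
    return mapping


def read_tracks_csv(
    path,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    flow_axis=(1.0, 0.0),
) -> TrackTable:
    """Read a TrackMate-style or generic track CSV into a :class:`TrackTable`.

    Positions are multiplied by ``pixel_size`` (pass 1.0 when the file is
    already in physical units, as TrackMate exports are); times are
    ``frame * frame_interval``.  Tracks with fewer than two samples are
    dropped with a logged count.  A ``wall_distance`` column, when present,
    populates the side-wall metadata.
    """
    df = pd.read_csv(path)
    mapping = _resolve_dialect(df.columns)
    sub = df[list(mapping.values())].apply(pd.to_numeric, errors="coerce")
    # TrackMate spot exports carry up to three non-numeric sub-header rows
    keep = sub.notna().all(axis=1)
    sub = sub[keep]
    wall_col = next((c for c in _WALL_DISTANCE_COLUMNS if c in df.columns), None)
    wall = pd.to_numeric(df[wall_col], errors="coerce")[keep] if wall_col else None

    trajectories: list[Trajectory] = []
    wall_distance: dict = {}
    n_dropped = 0
    axis = np.asarray(flow_axis, dtype=float)
    for track_id, grp in sub.groupby(mapping["track"], sort=True):
        frames = grp[mapping["frame"]].to_numpy()
        if frames.size < 2:
            n_dropped += 1
            continue
        if not np.all(np.diff(frames) > 0):
            raise TrackDataError(
                f"track {track_id!r}: frames are not strictly increasing"
            )
        trajectories.append(
            Trajectory(
                track_id=_canonical_id(track_id),
                times=frames * frame_interval,
                x=grp[mapping["x"]].to_numpy() * pixel_size,
                y=grp[mapping["y"]].to_numpy() * pixel_size,
                flow_axis=axis,
            )
        )
        if wall is not None:
            wall_distance[_canonical_id(track_id)] = float(wall.loc[grp.index].iloc[0])
    if n_dropped:
        logger.info("dropped %d track(s) with < 2 samples", n_dropped)
    return TrackTable(
        trajectories=trajectories,
        frame_interval=frame_interval,
        pixel_size=pixel_size,
        wall_distance=wall_distance or None,
    )


def _canonical_id(track_id):
    # CSV round-trips turn ints into floats; normalise integral ids back
    if isinstance(track_id, float) and float(track_id).is_integer():
        return int(track_id)
    return track_id


def write_tracks_csv(table: TrackTable, path) -> None:
    """Write a :class:`TrackTable` as a generic-dialect CSV.

    ``read_tracks_csv(write_tracks_csv(t))`` is the identity on
    (track_id, times, x, y) to six decimals.
    """
    rows = []
    for traj in table:
        frames = np.rint(traj.times / table.frame_interval).astype(int)
        for f, x, y in zip(frames, traj.x, traj.y):
            row = {"track": traj.track_id, "frame": f, "x": x, "y": y}
            if table.wall_distance is not None:
                row["wall_distance"] = table.wall_distance.get(traj.track_id, np.nan)
            rows.append(row)
    columns = ["track", "frame", "x", "y"]
    if table.wall_distance is not None:
        columns.append("wall_distance")
    pd.DataFrame(rows, columns=columns).to_csv(
        path, index=False, float_format="%.6f"
    )


def project_displacement(traj: Trajectory, t0: float) -> DisplacementSeries:
    """Displacement along the flow axis relative to the position at ``t0``.

    s(t) = ((x, y)(t) - (x, y)(t0)) · flow_axis for t >= t0, in µm; positive
    along the flow direction and s(t0) = 0.  The reference position is
    linearly interpolated when ``t0`` falls between samples.
    """
    t = traj.times
    if not (t[0] <= t0 <= t[-1]):
        raise ValueError(f"t0={t0} outside track span [{t[0]}, {t[-1]}]")
    ref = np.array([np.interp(t0, t, traj.x), np.interp(t0, t, traj.y)])
    eps = 1e-12 * max(1.0, abs(t0))
    mask = t >= t0 - eps
    disp = (
        (traj.x[mask] - ref[0]) * traj.flow_axis[0]
        + (traj.y[mask] - ref[1]) * traj.flow_axis[1]
    )
    times = t[mask]
    if not np.isclose(times[0], t0, atol=eps, rtol=0):
        times = np.concatenate([[t0], times])
        disp = np.concatenate([[0.0], disp])
    return DisplacementSeries(times=times, values=disp)


def estimate_velocity(series: DisplacementSeries) -> VelocityEstimate:
    """Ordinary least-squares speed of a displacement series, in m/s.

    Requires at least five samples (QC minimum).  A constant series is
    reported as zero speed with the ``"degenerate"`` flag; fits with
    r² < 0.8 carry the ``"low_r2"`` flag but are not rejected.
    """
    if series.n_samples < MIN_VELOCITY_SAMPLES:
        raise QCError(
            f"velocity fit needs >= {MIN_VELOCITY_SAMPLES} samples, "
            f"got {series.n_samples}"
        )
    span = float(series.times[-1] - series.times[0])
    if span <= 0:
        raise ValueError("zero time span")
    values = np.asarray(series.values, dtype=float)
    if np.allclose(values, values[0]):
        return VelocityEstimate(speed=0.0, sign=1, r_squared=0.0, flag="degenerate")
    fit = stats.linregress(series.times, values)
    slope_m_per_s = fit.slope * 1e-6  # µm/s -> m/s
    r2 = float(fit.rvalue**2)
    flag = None if r2 >= MIN_VELOCITY_R2 else "low_r2"
    return VelocityEstimate(
        speed=abs(slope_m_per_s),
        sign=1 if fit.slope >= 0 else -1,
        r_squared=r2,
        flag=flag,
    )


def filter_side_wall(
    table: TrackTable, min_distance: float = DEFAULT_WALL_DISTANCE_UM
) -> TrackTable:
    """Retain tracks farther than ``min_distance`` (µm) from the side walls.

    Measurements close to the side walls sit outside the region where the
    parallel-plate velocity profile holds, so they are excluded before any
    force estimate.
    """
    if table.wall_distance is None:
        raise ConfigurationError("track table has no side-wall distance metadata")
    kept, wall = [], {}
    for traj in table:
        try:
            d = table.wall_distance[traj.track_id]
        except KeyError:
            raise ConfigurationError(
                f"no side-wall distance for track {traj.track_id!r}"
            ) from None
        if d > min_distance:
            kept.append(traj)
            wall[traj.track_id] = d
    removed = len(table) - len(kept)
    if removed:
        logger.info("side-wall filter removed %d of %d tracks", removed, len(table))
    return TrackTable(
        trajectories=kept,
        frame_interval=table.frame_interval,
        pixel_size=table.pixel_size,
        wall_distance=wall,
    )
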