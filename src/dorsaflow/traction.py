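"""Dorsal traction forces from bead displacement against flow.

A ligand-coated bead bound to receptors on the upper surface of a cell is
pushed downstream by a gentle flow; when the cell's actomyosin machinery
pulls the bead upstream instead, the cell must be generating a traction
force at least equal to the applied hydrodynamic force plus the drag the
bead experiences while translating through the cell-medium interface:

    F_C = F_A + F_D        (magnitudes, along the flow axis)

F_A comes from the hydrodynamic calibration; F_D = 6πa·µ_c·u·f(θ), where µ_c
is the viscosity of the cortical protein network under the membrane, u the
bead speed, and f(θ) the drag coefficient of a sphere translating while
half-embedded at an interface with contact angle θ (f = 0.5 at θ = 90°).

The same balance applies to magnet-driven beads (F_C = F_M + F_D), with the
magnetic force calibrated from the drag on free beads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import QCError
from .hydro_calibration import HydroContext, ParticleProperties, drag_force
from .trajectories import (
    TrackTable,
    Trajectory,
    estimate_velocity,
    project_displacement,
)


def interfacial_drag_coefficient(theta: float) -> float:
    """Drag coefficient f(θ) of a sphere translating at a fluid-fluid interface.

    f(θ) = 0.5·[1 + (9/16)cos θ − 0.139·cos²θ] for contact angle θ in (0, π);
    f(π/2) = 0.5 (half-immersed sphere).
    """
    if not (0.0 < theta < math.pi):
        raise ValueError(f"contact angle {theta} outside (0, pi)")
    c = math.cos(theta)
    return 0.5 * (1.0 + (9.0 / 16.0) * c - 0.139 * c * c)


class InterfaceModel(BaseModel):
    """Cell-medium interface seen by a translating bead.

    ``cortical_viscosity`` (Pa·s) is the effective viscosity of the cortical
    protein network under the plasma membrane; at the minutes timescale of
    these measurements the cortex behaves as a viscous fluid.  The default
    550 Pa·s matches the flow viscosity obtained from the creep fits.
    ``contact_angle`` defaults to π/2 (beads half-enveloped by the membrane).
    """

    model_config = ConfigDict(frozen=True)

    cortical_viscosity: float = 550.0
    contact_angle: float = math.pi / 2.0

    @model_validator(mode="after")
    def _check(self) -> "InterfaceModel":
        if self.cortical_viscosity <= 0:
            raise ValueError("cortical viscosity must be > 0")
        if not (0.0 < self.contact_angle < math.pi):
            raise ValueError("contact angle must lie in (0, pi)")
        return self

    @property
    def drag_coefficient(self) -> float:
        return interfacial_drag_coefficient(self.contact_angle)


@dataclass(frozen=True)
class TractionResult:
    """Per-track force balance.  ``traction`` is None for flagged tracks."""

    track_id: object
    applied_force: float  # F_A, N
    interfacial_drag_force: float  # F_D, N
    traction: float | None  # F_C, N
    speed: float  # m/s
    sign: int  # -1 against flow, +1 with flow
    r_squared: float
    flag: str | None = None


def interfacial_drag(
    u: float, iface: InterfaceModel, particle: ParticleProperties
) -> float:
    """Interfacial drag F_D = 6π·a·µ_c·u·f(θ) on a bead moving at speed ``u``."""
    if u < 0:
        raise ValueError("speed must be >= 0")
    return (
        6.0
        * math.pi
        * particle.radius
        * iface.cortical_viscosity
        * u
        * iface.drag_coefficient
    )


def traction_force(
    traj: Trajectory,
    applied: float,
    iface: InterfaceModel,
    particle: ParticleProperties,
) -> TractionResult:
    """Traction force F_C = F_A + F_D for one bead track.

    The bead speed comes from the OLS velocity of the displacement projected
    on the flow axis.  The balance presumes the cell pulls the bead against
    the flow; a track moving with the flow is returned flagged (``with_flow``)
    with the traction unset rather than reported as a negative force.
    """
    series = project_displacement(traj, float(traj.times[0]))
    est = estimate_velocity(series)
    f_d = interfacial_drag(est.speed, iface, particle)
    if est.speed > 0 and est.sign > 0:
        return TractionResult(
            track_id=traj.track_id,
            applied_force=applied,
            interfacial_drag_force=f_d,
            traction=None,
            speed=est.speed,
            sign=est.sign,
            r_squared=est.r_squared,
            flag="with_flow",
        )
    return TractionResult(
        track_id=traj.track_id,
        applied_force=applied,
        interfacial_drag_force=f_d,
        traction=applied + f_d,
        speed=est.speed,
        sign=est.sign,
        r_squared=est.r_squared,
        flag=est.flag,
    )


def traction_table(
    table: TrackTable,
    applied: float,
    iface: InterfaceModel,
    particle: ParticleProperties,
    include: set | None = None,
) -> pd.DataFrame:
    """Batch traction estimate over a track table.

    ``include`` restricts the analysis to an explicit list of track ids (the
    operator's selection of non-aggregated single particles).  Tracks failing
    velocity QC are kept as flagged rows with NaN forces.
    """
    rows = []
    for traj in table:
        if include is not None and traj.track_id not in include:
            continue
        try:
            res = traction_force(traj, applied, iface, particle)
        except QCError:
            rows.append(
                {
                    "track_id": traj.track_id,
                    "u_m_per_s": float("nan"),
                    "F_A_N": applied,
                    "F_D_N": float("nan"),
                    "F_C_N": float("nan"),
                    "r2": float("nan"),
                    "flag": "qc_fail",
                }
            )
            continue
        rows.append(
            {
                "track_id": res.track_id,
                "u_m_per_s": res.speed,
                "F_A_N": res.applied_force,
                "F_D_N": res.interfacial_drag_force,
                "F_C_N": float("nan") if res.traction is None else res.traction,
                "r2": res.r_squared,
                "flag": res.flag or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["track_id", "u_m_per_s", "F_A_N", "F_D_N", "F_C_N", "r2", "flag"],
    )


def magnetic_force_calibration(
    free_tracks: TrackTable, ctx: HydroContext
) -> pd.DataFrame:
    """Magnetic force per position from free (unbound) bead tracks.

    The magnet force on a free bead balances the drag it experiences, so
    F_M = 6π·a·µ·u_free·C from each free-bead velocity.  The returned frame
    carries one row per track (track_id, u_m_per_s, F_M_N); F_M then enters
    the same balance as the hydrodynamic force: F_C = F_M + F_D.
    """
    rows = []
    for traj in free_tracks:
        est = estimate_velocity(project_displacement(traj, float(traj.times[0])))
        rows.append(
            {
                "track_id": traj.track_id,
                "u_m_per_s": est.speed,
                "F_M_N": drag_force(est.speed, ctx),
            }
        )
    return pd.DataFrame(rows, columns=["track_id", "u_m_per_s", "F_M_N"])
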