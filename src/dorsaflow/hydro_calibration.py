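"""Semi-analytic hydrodynamic force calibration for a shallow flow channel.

The calibration answers one question: what drag force does the flow exert on
a bead sitting a given distance above the bottom wall of the channel, at a
given pump rate?  It is built from three closed-form ingredients instead of a
finite-volume CFD run:

1. the fully developed laminar profile between parallel plates, valid in the
   central region of a wide, shallow rectangular channel (aspect ratio 10:1
   here, and only tracks > 200 µm from the side walls are analysed);
2. Lagrangian advection of a sphere by the Schiller–Naumann drag law until it
   reaches terminal velocity (the momentum relaxation time of a 2.8 µm bead
   is well under a microsecond, so terminal velocity equals the local fluid
   velocity to high accuracy);
3. the wall-corrected Stokes drag on a sphere translating parallel to a
   plane wall, F = 6πaµuC with the Faxén-type correction factor C(d/2h).

Forces sampled on a grid of wall distances are then fitted with a 4-parameter
logistic, F(x) = (A1 − A2)/(1 + (x/x0)^p) + A2, which is the compact form a
user evaluates to convert a measured bead height into an applied force.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.constants import Avogadro
from scipy.optimize import curve_fit

from .errors import CalibrationError, ConvergenceError, ExtrapolationWarning

#: µl/min to m³/s
UL_PER_MIN = 1e-9 / 60.0

#: default wall-normal height grid for calibration, m (near-wall to mid-channel)
DEFAULT_HEIGHTS = np.array([2.0, 3.0, 5.0, 8.0, 10.0, 15.0, 25.0, 35.0, 50.0]) * 1e-6

#: particle Reynolds number above which the inertial drag multiplier is applied
RE_P_STOKES_CUTOFF = 1e-3


class ChannelGeometry(BaseModel):
    """Rectangular channel cross-section: width ``w`` × height ``H`` (m)."""

    model_config = ConfigDict(frozen=True)

    width: float = 1.0e-3
    height: float = 1.0e-4

    @model_validator(mode="after")
    def _check(self) -> "ChannelGeometry":
        if not (self.width > self.height > 0):
            raise ValueError("channel requires width > height > 0")
        return self


class FluidProperties(BaseModel):
    """Newtonian medium: dynamic viscosity (Pa·s) and density (kg/m³)."""

    model_config = ConfigDict(frozen=True)

    viscosity: float = 1.0e-3
    density: float = 1000.0

    @model_validator(mode="after")
    def _check(self) -> "FluidProperties":
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("fluid viscosity and density must be > 0")
        return self


class ParticleProperties(BaseModel):
    """Spherical bead: diameter (m) and material density (kg/m³)."""

    model_config = ConfigDict(frozen=True)

    diameter: float = 2.8e-6
    density: float = 1300.0

    @model_validator(mode="after")
    def _check(self) -> "ParticleProperties":
        if self.diameter <= 0 or self.density <= 0:
            raise ValueError("particle diameter and density must be > 0")
        return self

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def mass(self) -> float:
        return self.density * (4.0 / 3.0) * math.pi * self.radius**3


class HydroContext(BaseModel):
    """Bundle of geometry, fluid, particle and the reference bead height.

    ``reference_height`` is the distance of the particle centroid from the
    bottom surface (default 5 µm, the middle of the 3–8 µm range of cell
    heights); it sets the wall correction factor used for force estimates.
    """

    model_config = ConfigDict(frozen=True)

    geometry: ChannelGeometry = ChannelGeometry()
    fluid: FluidProperties = FluidProperties()
    particle: ParticleProperties = ParticleProperties()
    reference_height: float = 5.0e-6

    @model_validator(mode="after")
    def _check(self) -> "HydroContext":
        ratio = self.particle.diameter / (2.0 * self.reference_height)
        if not (0.0 < ratio <= 1.0):
            raise ValueError(
                "require 0 < d/(2h) <= 1: particle centroid cannot sit below "
                "contact height"
            )
        return self

    @property
    def correction_factor(self) -> float:
        return wall_correction_factor(self.particle.diameter, self.reference_height)

    def at_height(self, h: float) -> "HydroContext":
        return self.model_copy(update={"reference_height": h})


@dataclass(frozen=True)
class AdvectionState:
    """Terminal state of a particle advected at fixed wall-normal height."""

    position: float  # streamwise distance travelled, m
    particle_velocity: float  # m/s
    fluid_velocity: float  # m/s
    reynolds: float  # particle Reynolds number at final slip
    drag_coefficient: float  # Schiller-Naumann C_D at final slip
    slip_ratio: float  # |V_f - V_p| / |V_f|
    n_steps: int
    time: float


@dataclass
class ForceCalibration:
    """Logistic map from wall distance to applied drag force at one flow rate.

    F(x) = (A1 − A2)/(1 + (x/x0)^p) + A2 with x the distance from the bottom
    wall (m) and F in newtons.
    """

    flow_rate: float  # µl/min
    heights: np.ndarray  # m
    forces: np.ndarray  # N
    a1: float
    a2: float
    x0: float
    p: float
    r_squared: float

    def evaluate(self, x) -> np.ndarray | float:
        return _logistic(x, self.a1, self.a2, self.x0, self.p)

    def to_dict(self) -> dict:
        return {
            "flow_rate_ul_min": self.flow_rate,
            "heights_m": list(map(float, self.heights)),
            "forces_N": list(map(float, self.forces)),
            "A1": self.a1,
            "A2": self.a2,
            "x0": self.x0,
            "p": self.p,
            "r2": self.r_squared,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceCalibration":
        return cls(
            flow_rate=d["flow_rate_ul_min"],
            heights=np.asarray(d["heights_m"], dtype=float),
            forces=np.asarray(d["forces_N"], dtype=float),
            a1=d["A1"],
            a2=d["A2"],
            x0=d["x0"],
            p=d["p"],
            r_squared=d["r2"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ForceCalibration":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def channel_velocity(
    z: float,
    flow_rate: float,
    geometry: ChannelGeometry,
    fluid: FluidProperties | None = None,
) -> float:
    """Laminar streamwise fluid velocity at height ``z`` (m) above the bottom.

    Parallel-plate Poiseuille profile for the central region of a wide,
    shallow channel: u(z) = 6·u_mean·(z/H)(1 − z/H) with
    u_mean = Q/(wH).  ``flow_rate`` is in µl/min.  The viscosity drops out of
    a flow-rate-driven profile; ``fluid`` is accepted for interface symmetry.
    """
    H = geometry.height
    if not (0.0 <= z <= H):
        raise ValueError(f"z={z} outside channel [0, {H}]")
    if flow_rate <= 0:
        raise ValueError("flow rate must be > 0")
    u_mean = flow_rate * UL_PER_MIN / (geometry.width * H)
    zeta = z / H
    return 6.0 * u_mean * zeta * (1.0 - zeta)


def channel_velocity_duct(
    y: float,
    z: float,
    flow_rate: float,
    geometry: ChannelGeometry,
    n_terms: int = 51,
) -> float:
    """Full rectangular-duct series profile (optional mode).

    ``y`` is the spanwise coordinate in [0, w], ``z`` wall-normal in [0, H].
    Used to verify that the plate profile is accurate more than 200 µm from
    the side walls; the plate profile is the default everywhere else.
    """
    w, H = geometry.width, geometry.height
    if not (0.0 <= y <= w) or not (0.0 <= z <= H):
        raise ValueError("(y, z) outside the duct cross-section")
    if flow_rate <= 0:
        raise ValueError("flow rate must be > 0")
    Q = flow_rate * UL_PER_MIN
    shape = 0.0
    flux = 0.0
    for n in range(1, n_terms + 1, 2):
        k = n * math.pi / H
        # cosh ratio in overflow-safe form: cosh(a)/cosh(b) =
        # exp(a-b)(1+e^{-2a})/(1+e^{-2b}) for a, b >= 0
        a = abs(k * (y - w / 2.0))
        b = k * w / 2.0
        ratio = math.exp(a - b) * (1.0 + math.exp(-2.0 * a)) / (1.0 + math.exp(-2.0 * b))
        span = 1.0 - ratio
        shape += span * math.sin(k * z) / n**3
        flux += (2.0 * H / (n * math.pi)) / n**3 * (
            w - (2.0 * H / (n * math.pi)) * math.tanh(k * w / 2.0)
        )
    return Q * shape / flux


def wall_correction_factor(d: float, h: float) -> float:
    """Faxén-type drag correction for a sphere translating near a plane wall.

    C = [1 − (9/16)k + (1/8)k³ − (45/256)k⁴ − (1/16)k⁵]⁻¹ with k = d/(2h),
    where ``d`` is the particle diameter and ``h`` the distance of the
    particle centroid from the wall.  C → 1 far from the wall and grows as
    the particle approaches it.
    """
    k = d / (2.0 * h)
    if not (0.0 < k <= 1.0):
        raise ValueError(
            f"d/(2h) = {k:.3g} outside (0, 1]: centroid below contact height"
        )
    denom = (
        1.0
        - (9.0 / 16.0) * k
        + (1.0 / 8.0) * k**3
        - (45.0 / 256.0) * k**4
        - (1.0 / 16.0) * k**5
    )
    return 1.0 / denom


def schiller_naumann_cd(re_p: float) -> float:
    """Schiller–Naumann drag coefficient C_D = (24/Re_p)(1 + 0.15·Re_p^0.687)."""
    if re_p <= 0:
        raise ValueError("particle Reynolds number must be > 0")
    return (24.0 / re_p) * (1.0 + 0.15 * re_p**0.687)


def _sn_multiplier(re_p: float) -> float:
    """Inertial multiplier on Stokes drag, (1 + 0.15·Re_p^0.687)."""
    return 1.0 + 0.15 * re_p**0.687


def _logistic(x, a1, a2, x0, p):
    return (a1 - a2) / (1.0 + (x / x0) ** p) + a2


def advect_particle(
    z: float,
    flow_rate: float,
    ctx: HydroContext,
    duration: float = 0.05,
    dt: float | None = None,
    v0: float = 0.0,
    slip_tol: float = 1e-4,
) -> AdvectionState:
    """Advect a particle at fixed height ``z`` until it reaches terminal velocity.

    Integrates m·dV_p/dt = (1/8)π·ρ_f·d_p²·C_D·|V_f − V_p|(V_f − V_p) with the
    Schiller–Naumann C_D, which in slip velocity s = V_f − V_p reduces to
    ds/dt = −s·φ(Re_s)/τ_p with τ_p = m/(3πµd) and φ the inertial multiplier.
    Explicit Euler with dt = min(10 µs, τ_p/4); terminal when
    |V_f − V_p|/V_f < ``slip_tol``.
    """
    H = ctx.geometry.height
    if not (0.0 < z < H):
        raise ValueError(f"z={z} must lie strictly inside (0, {H})")
    vf = channel_velocity(z, flow_rate, ctx.geometry, ctx.fluid)
    mu = ctx.fluid.viscosity
    rho_f = ctx.fluid.density
    d = ctx.particle.diameter
    m = ctx.particle.mass
    tau_p = m / (3.0 * math.pi * mu * d)
    if dt is None:
        dt = min(1e-5, tau_p / 4.0)
    if dt <= 0:
        raise ValueError("dt must be > 0")

    vp = float(v0)
    pos = 0.0
    t = 0.0
    n = 0
    max_steps = int(math.ceil(duration / dt))
    slip = vf - vp
    while n < max_steps:
        if abs(slip) / vf < slip_tol:
            break
        re_s = rho_f * d * abs(slip) / mu
        phi = _sn_multiplier(re_s) if re_s > 0 else 1.0
        vp += dt * slip * phi / tau_p
        pos += vp * dt
        t += dt
        n += 1
        slip = vf - vp
    slip_ratio = abs(slip) / vf
    if slip_ratio >= slip_tol:
        raise ConvergenceError(
            f"advection did not converge in {duration} s: slip ratio {slip_ratio:.3g}"
        )
    re_final = rho_f * d * abs(slip) / mu
    cd_final = schiller_naumann_cd(re_final) if re_final > 0 else math.inf
    return AdvectionState(
        position=pos,
        particle_velocity=vp,
        fluid_velocity=vf,
        reynolds=re_final,
        drag_coefficient=cd_final,
        slip_ratio=slip_ratio,
        n_steps=n,
        time=t,
    )


def drag_force(u: float, ctx: HydroContext) -> float:
    """Wall-corrected Stokes drag on a particle moving at speed ``u`` (m/s).

    F = 6π·a·µ·u·C, with the Schiller–Naumann inertial multiplier
    (1 + 0.15·Re_p^0.687) applied once Re_p = ρdu/µ exceeds 1e-3; below that
    the correction is < 0.2 % and the pure Stokes form is used.
    """
    if u < 0:
        raise ValueError("speed must be >= 0")
    mu = ctx.fluid.viscosity
    a = ctx.particle.radius
    force = 6.0 * math.pi * a * mu * u * ctx.correction_factor
    re_p = ctx.fluid.density * ctx.particle.diameter * u / mu
    if re_p > RE_P_STOKES_CUTOFF:
        force *= _sn_multiplier(re_p)
    return force


def terminal_drag_force(z: float, flow_rate: float, ctx: HydroContext) -> float:
    """Drag on a bead held at height ``z`` in a flow at ``flow_rate`` (µl/min).

    Advects the particle to terminal velocity at ``z`` and evaluates the
    wall-corrected drag with the correction factor for that height.  This is
    the per-height sample from which calibrations are built.
    """
    state = advect_particle(z, flow_rate, ctx)
    return drag_force(state.particle_velocity, ctx.at_height(z))


def build_calibration(
    flow_rate: float,
    ctx: HydroContext,
    heights: np.ndarray | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> ForceCalibration:
    """Simulate drag forces over a height grid and fit the logistic model.

    Initialisation: A1 = min force, A2 = max force, x0 = median height,
    p = 2, with ``n_restarts`` log-jittered x0 multi-starts (fixed seed);
    the best-SSE fit wins.  p is bounded to (0, 10].
    """
    if heights is None:
        heights = DEFAULT_HEIGHTS
    heights = np.sort(np.asarray(heights, dtype=float))
    if heights.size < 6:
        raise CalibrationError(
            f"need >= 6 heights spanning near-wall to mid-channel, got {heights.size}"
        )
    forces = np.array([terminal_drag_force(h, flow_rate, ctx) for h in heights])
    (a1, a2, x0, p), r2, residuals = fit_logistic(
        heights, forces, n_restarts=n_restarts, seed=seed
    )
    if r2 <= 0.95:
        raise CalibrationError(
            f"logistic fit quality r²={r2:.4f} <= 0.95 at {flow_rate} µl/min; "
            f"residuals: {residuals}"
        )
    return ForceCalibration(
        flow_rate=flow_rate,
        heights=heights,
        forces=forces,
        a1=a1,
        a2=a2,
        x0=x0,
        p=p,
        r_squared=r2,
    )


def fit_logistic(
    x: np.ndarray,
    f: np.ndarray,
    n_restarts: int = 5,
    seed: int = 0,
) -> tuple[tuple[float, float, float, float], float, np.ndarray]:
    """Fit F(x) = (A1 − A2)/(1 + (x/x0)^p) + A2 by nonlinear least squares.

    Fitting happens in scaled units (x in units of its median, F in units of
    its maximum) to keep the optimiser well conditioned; A1, A2 and x0 are
    rescaled on return and p is scale invariant.  Multi-start with
    ``n_restarts`` log-jittered x0 at a fixed seed; best SSE wins; p is
    bounded to (0, 10].  Returns ((A1, A2, x0, p), r², residuals).
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    h_scale = float(np.median(x))
    f_scale = float(np.max(np.abs(f)))
    hs = x / h_scale
    fs = f / f_scale

    rng = np.random.default_rng(seed)
    lower = [0.0, 0.0, 1e-6, 1e-6]
    upper = [np.inf, np.inf, np.inf, 10.0]
    best = None
    residuals = None
    for i in range(n_restarts):
        x0_try = 1.0 if i == 0 else float(rng.lognormal(0.0, 0.5))
        p0 = [fs.min(), fs.max(), x0_try, 2.0]
        try:
            popt, _ = curve_fit(
                _logistic, hs, fs, p0=p0, bounds=(lower, upper), maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        resid = fs - _logistic(hs, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[0]:
            best = (sse, popt)
            residuals = resid * f_scale
    if best is None:
        raise CalibrationError(
            f"logistic fit did not converge in {n_restarts} restarts"
        )
    sse, popt = best
    sst = float(np.sum((fs - fs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    params = (
        float(popt[0]) * f_scale,
        float(popt[1]) * f_scale,
        float(popt[2]) * h_scale,
        float(popt[3]),
    )
    return params, r2, residuals


def applied_force(x: float, cal: ForceCalibration) -> float:
    """Applied hydrodynamic force at wall distance ``x`` (m) from a calibration.

    Evaluates the fitted logistic; warns when ``x`` lies outside the sampled
    height span (extrapolation).
    """
    if x <= 0:
        raise ValueError("wall distance must be > 0")
    if x < cal.heights.min() or x > cal.heights.max():
        warnings.warn(
            f"x={x:.3g} m outside calibrated span "
            f"[{cal.heights.min():.3g}, {cal.heights.max():.3g}] m",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(cal.evaluate(x))


def ligands_per_particle(
    bound_mass_ug: float = 8.0,
    molecular_weight: float = 150.0,
    particles_per_mg: float = 6.09e8,
) -> tuple[float, float]:
    """Ligand accounting for protein-G beads saturated with IgG-class ligand.

    ``bound_mass_ug`` is the ligand mass bound per mg of beads (manufacturer:
    ~8 µg IgG/mg) and ``molecular_weight`` the g/mol figure used in the
    original accounting.  Returns (molecules per mg of beads, ligands per
    particle rounded to one significant figure).
    """
    if bound_mass_ug <= 0 or molecular_weight <= 0 or particles_per_mg <= 0:
        raise ValueError("all inputs must be > 0")
    molecules = bound_mass_ug * 1e-6 / molecular_weight * Avogadro
    per_particle = molecules / particles_per_mg
    magnitude = 10.0 ** math.floor(math.log10(per_particle))
    return molecules, round(per_particle / magnitude) * magnitude
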