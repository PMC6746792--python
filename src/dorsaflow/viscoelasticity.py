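"""Kelvin–Voigt four-element creep-compliance fitting for whole cells.

Under a constant hydrodynamic force F_A, a cell-bound bead displaces along
the flow by X(t); the creep compliance of the cell follows as

    J(t) = 6πa·C·X(t) / F_A

with a the bead radius and C the wall correction factor.  J(t) is fitted
with the four-element (Burgers) model — a Maxwell arm (spring G_0, dashpot
µ'_0) in series with a Kelvin–Voigt arm (spring G_1, dashpot µ'_1):

    J(t) = (1/G_0)·[1 − (G_1/(G_0+G_1))·exp(−t/τ)] + t/µ'_0,
    τ = µ'_1·(G_0+G_1)/(G_0·G_1)

giving an instantaneous elastic response 1/(G_0+G_1), a delayed elastic
response with relaxation time τ, and steady viscous flow at rate 1/µ'_0.
Shear moduli convert to Young's moduli via E = 2G(1+ν) (ν = 0.4 by default);
the instantaneous stiffness E_0+E_1 is the headline quantity.

The creep window alone is fitted; the recovery after flow-off is predicted
by Boltzmann superposition and serves as out-of-sample validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, QCError, TrackDataError
from .hydro_calibration import HydroContext
from .trajectories import Trajectory, project_displacement

#: minimum samples / duration for a creep fit
MIN_FIT_SAMPLES = 20
MIN_FIT_DURATION = 5.0


@dataclass(frozen=True)
class CreepSeries:
    """Creep window of one track: displacement and compliance vs time.

    ``times`` are seconds since flow onset (first entry 0 with X = 0: the
    pre-step anchor), ``displacement`` in metres along the flow axis, and
    ``compliance`` = 6πa·C·X/F_A pointwise in 1/Pa.
    """

    times: np.ndarray
    displacement: np.ndarray
    compliance: np.ndarray
    applied_force: float
    context: HydroContext

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class CreepFitResult:
    """Fitted four-element parameters in shear and Young's forms."""

    g0: float  # shear modulus, Pa
    g1: float  # delayed shear modulus, Pa
    mu0_shear: float  # flow viscosity µ'_0, Pa·s
    mu1_shear: float  # delayed viscosity µ'_1, Pa·s
    tau: float  # relaxation time, s
    poisson_ratio: float
    e0: float  # Young's modulus, Pa
    e1: float  # delayed Young's modulus, Pa
    mu0: float  # converted flow viscosity, Pa·s
    mu1: float  # converted delayed viscosity, Pa·s
    e0_plus_e1: float  # instantaneous stiffness, Pa
    sse: float
    r_squared: float
    n_points: int


def geometry_prefactor(ctx: HydroContext) -> float:
    """6πa·C for the reference height of ``ctx`` (converts X to J and back)."""
    return 6.0 * math.pi * ctx.particle.radius * ctx.correction_factor


def compliance_from_displacement(
    traj: Trajectory,
    flow_on: float,
    flow_off: float,
    applied_force: float,
    ctx: HydroContext,
) -> CreepSeries:
    """Extract the creep window [flow_on, flow_off] of a track as compliance.

    Displacement is projected on the flow axis relative to the position at
    flow onset (positive along flow) and converted pointwise to compliance.
    """
    if applied_force <= 0:
        raise ValueError("applied force must be > 0")
    if not (flow_on < flow_off):
        raise ValueError("flow_on must precede flow_off")
    t = traj.times
    if flow_on < t[0] or flow_off > t[-1]:
        raise ValueError(
            f"creep window [{flow_on}, {flow_off}] outside track span "
            f"[{t[0]}, {t[-1]}]"
        )
    series = project_displacement(traj, flow_on)
    mask = series.times <= flow_off + 1e-12
    times = series.times[mask] - flow_on
    disp = series.values[mask] * 1e-6  # µm -> m
    compliance = geometry_prefactor(ctx) * disp / applied_force
    return CreepSeries(
        times=times,
        displacement=disp,
        compliance=compliance,
        applied_force=applied_force,
        context=ctx,
    )


def kv4_relaxation_time(g0: float, g1: float, mu1: float) -> float:
    """Relaxation time τ = µ'_1(G_0+G_1)/(G_0·G_1) of the delayed response."""
    return mu1 * (g0 + g1) / (g0 * g1)


def kv4_compliance(t, g0: float, g1: float, mu0: float, mu1: float):
    """Four-element creep compliance J(t), 1/Pa.

    J(0) = 1/(G_0+G_1) and dJ/dt → 1/µ'_0 as t → ∞.  Accepts scalar or
    array ``t`` >= 0.
    """
    if min(g0, g1, mu0, mu1) <= 0:
        raise ValueError("all four parameters must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    tau = kv4_relaxation_time(g0, g1, mu1)
    out = (1.0 / g0) * (1.0 - (g1 / (g0 + g1)) * np.exp(-t / tau)) + t / mu0
    return out if out.ndim else float(out)


def convert_moduli(g: float, poisson_ratio: float = 0.4) -> float:
    """Convert a shear quantity to its Young's form: E = 2G(1+ν).

    Applies equally to moduli (Pa) and viscosities (Pa·s); linear in G.
    """
    if not (0.0 <= poisson_ratio <= 0.5):
        raise ValueError("Poisson ratio must lie in [0, 0.5]")
    return 2.0 * g * (1.0 + poisson_ratio)


def _kv4_model(t, g0, g1, mu0, mu1):
    # unchecked fast path for the optimiser
    tau = mu1 * (g0 + g1) / (g0 * g1)
    return (1.0 / g0) * (1.0 - (g1 / (g0 + g1)) * np.exp(-t / tau)) + t / mu0


def _kv4_model_tied(t, g0, g1, mu1):
    return _kv4_model(t, g0, g1, mu1, mu1)


def fit_kv4(
    series: CreepSeries,
    poisson_ratio: float = 0.4,
    n_restarts: int = 5,
    seed: int = 0,
    tied: bool = False,
) -> CreepFitResult:
    """Nonlinear least-squares fit of the four-element model to a creep window.

    The pre-step anchor sample (t = 0, J = 0) is excluded: the model's
    instantaneous response makes J(0⁺) = 1/(G_0+G_1) > 0 while the recorded
    frame at flow onset predates the force step.  Initialisation is
    data-driven (G_0+G_1 from the first compliance sample, µ'_0 from the
    terminal slope, G_0 from the late-time elastic plateau, τ from the
    half-rise time), with ``n_restarts`` log-jittered multi-starts at a
    fixed seed; the best-SSE fit wins.  ``tied=True`` constrains
    µ'_0 = µ'_1 (the three-parameter single-viscosity variant).
    """
    keep = series.times > 0
    t = series.times[keep]
    j = series.compliance[keep]
    if t.size < MIN_FIT_SAMPLES:
        raise QCError(f"creep fit needs >= {MIN_FIT_SAMPLES} samples, got {t.size}")
    if t[-1] - t[0] < MIN_FIT_DURATION:
        raise QCError(
            f"creep fit needs >= {MIN_FIT_DURATION} s of data, got "
            f"{t[-1] - t[0]:.2f} s"
        )

    # data-driven initial guesses
    n_tail = max(5, t.size // 4)
    tail_slope = float(np.polyfit(t[-n_tail:], j[-n_tail:], 1)[0])
    if tail_slope <= 0:
        raise TrackDataError("negative terminal compliance slope: not a creep curve")
    mu0_init = 1.0 / tail_slope
    j_el = j - t * tail_slope  # elastic part: instantaneous + delayed
    j_el0 = max(float(j[0] - t[0] * tail_slope), 1e-12)
    gsum_init = 1.0 / j_el0
    j_el_end = max(float(np.mean(j_el[-n_tail:])), j_el0 * 1.01)
    g0_init = 1.0 / j_el_end
    g1_init = max(gsum_init - g0_init, 0.05 * g0_init)
    half = 0.5 * (j_el0 + j_el_end)
    above = np.nonzero(j_el >= half)[0]
    t_half = float(t[above[0]]) if above.size else float(t[t.size // 2])
    tau_init = max(t_half / math.log(2.0), float(t[0]) / 10.0)
    mu1_init = tau_init * g0_init * g1_init / (g0_init + g1_init)

    # physical plausibility bounds for cellular material: moduli between
    # 0.01 Pa and 1 MPa, viscosities between 0.01 and 1e8 Pa·s
    if tied:
        model, p_init = _kv4_model_tied, np.array([g0_init, g1_init, mu1_init])
        bounds = ([1e-2, 1e-2, 1e-2], [1e6, 1e6, 1e8])
    else:
        model, p_init = _kv4_model, np.array([g0_init, g1_init, mu0_init, mu1_init])
        bounds = ([1e-2, 1e-2, 1e-2, 1e-2], [1e6, 1e6, 1e8, 1e8])
    p_init = np.clip(p_init, bounds[0], bounds[1])

    rng = np.random.default_rng(seed)
    best = None
    for i in range(n_restarts):
        p0 = p_init if i == 0 else np.clip(
            p_init * rng.lognormal(0.0, 0.3, p_init.size), bounds[0], bounds[1]
        )
        try:
            popt, _ = curve_fit(
                model, t, j, p0=p0, bounds=bounds, maxfev=20000,
                x_scale=np.abs(p0), ftol=1e-10, xtol=1e-10, gtol=1e-10,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((j - model(t, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError(
            f"creep fit failed in all {n_restarts} restarts "
            f"(n={t.size}, span={t[-1] - t[0]:.1f} s)"
        )
    sse, popt = best
    if tied:
        g0, g1, mu1 = map(float, popt)
        mu0 = mu1
    else:
        g0, g1, mu0, mu1 = map(float, popt)
    sst = float(np.sum((j - j.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return CreepFitResult(
        g0=g0,
        g1=g1,
        mu0_shear=mu0,
        mu1_shear=mu1,
        tau=kv4_relaxation_time(g0, g1, mu1),
        poisson_ratio=poisson_ratio,
        e0=convert_moduli(g0, poisson_ratio),
        e1=convert_moduli(g1, poisson_ratio),
        mu0=convert_moduli(mu0, poisson_ratio),
        mu1=convert_moduli(mu1, poisson_ratio),
        e0_plus_e1=convert_moduli(g0 + g1, poisson_ratio),
        sse=sse,
        r_squared=r2,
        n_points=int(t.size),
    )


def recovery_curve(
    t_prime,
    fit: CreepFitResult,
    t_on_duration: float,
    applied_force: float,
    ctx: HydroContext,
):
    """Predicted displacement (m) at time ``t_prime`` >= 0 after flow-off.

    Boltzmann superposition of a force step on at t = 0 and off at
    t = t_on_duration:

        X(t_off + t') = (F_A/(6πaC)) · [J(t_on + t') − J(t')]

    At t' = 0 this equals the creep endpoint minus the instantaneous elastic
    recoil F_A/(6πaC·(G_0+G_1)); as t' → ∞ it tends to the residual viscous
    displacement (F_A/(6πaC))·t_on/µ'_0.
    """
    t_prime = np.asarray(t_prime, dtype=float)
    if np.any(t_prime < 0):
        raise ValueError("t_prime must be >= 0")
    pref = applied_force / geometry_prefactor(ctx)
    out = pref * (
        _kv4_model(t_on_duration + t_prime, fit.g0, fit.g1, fit.mu0_shear, fit.mu1_shear)
        - _kv4_model(t_prime, fit.g0, fit.g1, fit.mu0_shear, fit.mu1_shear)
    )
    return out if out.ndim else float(out)
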