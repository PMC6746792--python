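# Methods

## Overview

`dorsaflow` turns trajectories of receptor-bound microbeads in a shallow
flow channel into forces and material parameters. Every measurement reduces
to a scalar displacement along the flow axis; every force estimate passes
through one hydrodynamic calibration. This note records the models, the
defaults and why, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## Hydrodynamic calibration

**Model.** The channel (width w = 1 mm, height H = 100 µm) carries fully
developed laminar flow. In the central region — aspect ratio 10:1, and all
analyses exclude tracks within 200 µm of the side walls — the velocity
profile is the parallel-plate Poiseuille form
`u(z) = 6 u_mean (z/H)(1 − z/H)`, `u_mean = Q/(wH)`. A full rectangular-duct
series solution is available (`channel_velocity_duct`) as an optional mode;
it shows the central profile has the plate *shape* but is uniformly higher
by the side-wall flux-deficit factor `1/(1 − 0.63 H/w) ≈ 1.067`. The plate
normalisation is retained as the default because it reproduces the platform's
benchmark forces within ~7 % and keeps the calibration closed-form; the
duct mode quantifies the residual bias.

**Particle dynamics.** A bead held at height z is advected by
`m dV_p/dt = (1/8)π ρ_f d_p² C_D |V_f − V_p|(V_f − V_p)` with the
Schiller–Naumann drag coefficient `C_D = (24/Re_p)(1 + 0.15 Re_p^0.687)`.
In slip velocity this is `ds/dt = −s φ(Re_s)/τ_p` with momentum relaxation
time `τ_p = m/(3πµd) ≈ 0.57 µs` for a 2.8 µm, 1300 kg/m³ bead in water, so
terminal velocity (equal to the local fluid velocity; no gravity, lift or
Brownian term is modelled) is reached in microseconds. Explicit Euler with
`dt = min(10 µs, τ_p/4)` and a slip tolerance of 1e-4 converges in a few
dozen steps.

**Drag force.** `F_A = 6π a µ u C` with the near-wall correction
`C(k = d/2h) = [1 − (9/16)k + (1/8)k³ − (45/256)k⁴ − (1/16)k⁵]⁻¹`, and the
Schiller–Naumann multiplier applied for `Re_p > 1e-3` (continuity with the
advection model; the correction is < 0.2 % below the cutoff). At the
reference height h = 5 µm, C = 1.1848. h defaults to 5 µm — the middle of
the 3–8 µm range of heights of well-spread adherent cells, where C varies
only weakly — and is configurable; values outside 3–8 µm trigger a warning.

**Fluid and particle defaults.** µ = 1.0e-3 Pa·s, ρ = 1000 kg/m³ (aqueous
culture medium at room temperature), d = 2.8 µm, ρ_p = 1300 kg/m³
(streptavidin/protein-G dynabeads). With these, the calibration spans
≈ 14.9 pN (10 µl/min) to ≈ 2.1 nN (1400 µl/min) at h = 5 µm.

**Logistic condensation.** Per flow rate, forces are computed on a 9-point
height grid (2–50 µm wall-normal) and fitted with
`F(x) = (A1 − A2)/(1 + (x/x0)^p) + A2` by nonlinear least squares in scaled
units (heights over their median, forces over their maximum), with
initialisation A1 = min F, A2 = max F, x0 = median height, p = 2, bounds
p ∈ (0, 10], and five x0-jittered restarts at a fixed seed (best SSE wins).
The fit exceeds r² = 0.95 at every flow rate used (typically 0.999); a fit
below that threshold raises an error rather than silently degrading force
estimates.

## Traction forces

The balance is scalar, along the flow axis: `F_C = F_A + F_D` for a bead
moving against the flow (magnitudes added). The bead speed comes from an
ordinary least-squares fit of projected displacement versus time, requiring
at least 5 samples; fits with r² < 0.8 are flagged, not dropped, so constant
velocity — the model's assumption — can be audited per track. With-flow
motion is flagged (`with_flow`) instead of yielding a negative traction.
Magnet-driven measurements use the identical balance with F_M (calibrated
from free-bead drag) in place of F_A.

Interfacial drag: `F_D = 6π a µ_c u f(θ)`,
`f(θ) = 0.5[1 + (9/16)cos θ − 0.139 cos²θ]`. Defaults θ = π/2 (beads
observed half-enveloped by the membrane) and µ_c = 550 Pa·s, the flow
viscosity of the cortical network at the minutes timescale, consistent with
the creep fits; both are configuration inputs. Over θ ∈ [π/3, 2π/3] the
relative deviation of f from f(π/2) peaks at ≈ 31.6 %, which bounds the
sensitivity of F_D to the contact-angle estimate.

Selection of non-aggregated single beads is an explicit include-list of
track ids, not an automatic detector: no robust aggregation criterion
exists at 10X bright field.

## Viscoelasticity

**Model.** Creep compliance of the four-element (Burgers) model,

    J(t) = (1/G0)[1 − (G1/(G0+G1)) exp(−t/τ)] + t/µ′0,
    τ = µ′1 (G0+G1)/(G0 G1),

with four independent parameters: the flow viscosity µ′0 (steady slope) and
the delayed viscosity µ′1 (inside τ) are distinct, since the platform
reports E0, E1, µ0, µ1 and τ as separate quantities. A tied
single-viscosity variant (µ′0 = µ′1, three parameters) is available for
comparison. Conversion to Young's form is `E = 2G(1+ν)`, ν = 0.4 by default
(measured Poisson ratios of adherent cells span 0.4–0.5; configurable in
that range).

**Fitting.** J(t) (equivalently X(t) up to the constant `6πaC/F_A`) is
fitted over the creep window only; the recovery window is predicted by
Boltzmann superposition, `X(t_off + t′) = (F_A/6πaC)[J(t_on + t′) − J(t′)]`,
and serves as out-of-sample validation. Note the superposition implies an
instantaneous elastic recoil `F_A/(6πaC (G0+G1))` at flow-off (≈ 70 nm at
the default parameters), so the first recovery frame sits slightly below
the creep endpoint. The frame recorded at flow onset predates the force
step (X = 0 there); it is excluded from the fit because the model's
instantaneous response makes J(0⁺) > 0. Initialisation is data-driven —
G0+G1 from the first compliance sample, µ′0 from the terminal slope, G0
from the late-time elastic plateau, τ from the half-rise time — with five
log-jittered restarts at a fixed seed. Parameters are bounded to a broad
physical range (moduli 0.01 Pa–1 MPa, viscosities 0.01–1e8 Pa·s); a
negative terminal slope raises a data error (the window is not a creep
response).

**Identifiability.** On noiseless synthetic creep data the fit returns the
generating parameters to machine-level accuracy. With realistic
localisation noise the picture splits: G0 and especially µ′0 are well
constrained (the knee and the long linear tail), but at the default
conditions — 50 nm noise, 0.5 s frames, central parameters
(G0, G1, µ′0, µ′1) = (500, 200, 550, 50), i.e. τ = 0.35 s — the
delayed-elastic transient has displacement amplitude ≈ 28 nm and decays
within the first frame interval. It is therefore *below the noise floor*,
and G1, µ′1 and τ are not identifiable per cell: a Fisher-information
estimate puts sd(G1) around ten times G1 itself, and Monte-Carlo cohorts
confirm per-cell errors of that order, with the instantaneous stiffness
E0+E1 inheriting the uncertainty. This is a physical limit of the
measurement at these conditions, not a fitting defect; population-level
comparisons remain valid (cohorts probed at different forces from a shared
parameter population are statistically indistinguishable, as they should
be), and per-cell delayed parameters should be interpreted with caution
unless the transient is resolved (faster frames, or materials with longer
τ / larger G1 contrast).

## Bond strength

The ramp applies strictly increasing flow rates (default 200–1400 µl/min,
200 µl/min steps, 30 s/step — 7 steps, 210 s) with per-step forces from the
calibration at the reference height (≈ 0.3–2.1 nN). A bead counts as
detached at a step if its track fails to span the step or its along-flow
displacement within the step exceeds 5 µm — far above any creep motion at
these forces — and detachment is absorbing. Counts are indexed so that
entry 0 is the cohort at ramp start and the drop into entry k is attributed
to step k's force; replicates are pooled before survival analysis. The
rupture force is the step force with the largest fractional single-step
loss (earliest step on ties), a step-resolution lower bound on the true
threshold; no interpolation between steps and no loading-rate (Bell-type)
extrapolation is attempted — the measured quantity is the strength of a
multivalent bond cluster, not a single molecule. By this counting
convention the final step's own drop is structurally unobservable; rupture
thresholds are resolvable up to the second-to-last step force.

## Synthetic data

Generators emulate the statistical structure each mode assumes, with ground
truth stored alongside: constant per-bead upstream speeds (log-normal,
median 20 nm/s, log-sd 0.3) for traction; four-element creep plus
superposed recovery for viscoelasticity (per-cell parameters log-normal
around the central values, log-sd 0.3, putting mean E0+E1 near 2 kPa);
threshold-triggered track termination for the ramp, with either a single
sharp low-force threshold component or a bimodal mixture (27 % between the
first two step forces, 73 % beyond the ramp maximum). Frame intervals and
durations follow the imaging protocols of the modes (10 s/5 min, 0.5 s/3
min, 1 s/ramp). Localisation noise is i.i.d. Gaussian, σ = 50 nm per
coordinate per frame (~0.1 px at 10X); no drift, no Brownian term (bound
beads; thermal motion is below the noise floor at this bead size), no
aggregation, no out-of-focus effects. All generators are bit-reproducible
under a fixed seed.

What passing tests show: the pipeline inverts its own generating models —
force balances, compliance algebra, survival bookkeeping — at the stated
noise levels, and the calibration reproduces the platform's published force
spectrum within 10 %. What they cannot show: agreement with real cells
(population moduli and rupture patterns of the original experiments arise
from live-cell heterogeneity the generators only caricature), tracking
failures on real bright-field images, or drift/aggregation artefacts.

A minimal imaging front-end (Gaussian spots, Poisson shot noise; detection
by thresholded connected components with intensity-weighted centroids;
greedy nearest-neighbour linking with a displacement gate, no gap closing)
exists to exercise the tracking entry point on synthetic stacks; it is not
a substitute for a production tracker on real data.

## Numerical and interface choices

- SI units internally; µl/min, µm and pN at the boundaries, converted once.
- Time zero is acquisition start; frames are 0-based; flow on/off times are
  configuration inputs, not inferred.
- Velocity fits: `scipy.stats.linregress`; nonlinear fits:
  `scipy.optimize.curve_fit` (trust-region reflective with bounds),
  multi-start with fixed seeds, tolerances 1e-10 and per-parameter scaling.
- A constant displacement series reports zero speed with a `degenerate`
  flag rather than an undefined r².
- Ties in the rupture-step argmax resolve to the earliest step.
- CSV round trips preserve values to six decimals; track ids and all QC
  removals are logged, never silent.

## Known limitations

- The plate-profile calibration carries a ~6–7 % systematic deficit
  relative to the duct solution (see above); both are far smaller than
  bead-height uncertainty across the 3–8 µm cell-height range.
- No entrance-region or developing-flow modelling; calibrations assume the
  imaging field sits in the fully developed region.
- Per-cell delayed viscoelastic parameters are noise-limited at the default
  acquisition settings (see Identifiability).
- The interfacial drag model assumes a clean fluid–fluid interface with
  θ constant per experiment; membrane heterogeneity is not modelled.
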