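# Methods

This note records the models implemented in `coaflow`, the choices made
where the design was genuinely open, and what the test suite does and does
not establish.  Units throughout the 0D model are clinical: mL, s, mmHg,
cm², with blood density ρ = 1.05 g/cm³, dynamic viscosity 0.0035 Pa·s and
1 mmHg = 1333.22 dyn/cm².

## The 0D circulation model

### Topology

A prescribed pulmonary inflow fills the left atrium; the left atrium and
ventricle are time-varying elastance chambers; the mitral and aortic
valves, their regurgitant counterparts and the coarctation are
net-pressure-gradient elements; the arterial side is a two-node
Windkessel:

```
Q_PV(t) → LA → MV → LV → AV → [C_ao] —R_ao— bifurcation
                                           ├─ R_ub ──────────────┐
                                           ├─ R_pda + COA element ┤→ [C_SAC] —R_SA—R_SV→ P_CV0
                                           └─ R_graft (post only) ┘
```

The pulmonary venous ladder of the source circuit (L_PV, R_PV, R_PVC,
C_PVC, L_PC, R_PC, R_PA, C_PA) is carried as documented constants but not
dynamically simulated: its elements have negligible influence on left-heart
output when the pulmonary inflow waveform is prescribed directly, which is
what the calibration pins down anyway.

### Elements

- **Chambers** — `P = E(t)·(V − V0)` with the double-Hill normalized
  elastance
  `E(t) = N·[(t/τ1)^m1/(1+(t/τ1)^m1)]·[1/(1+(t/τ2)^m2)] + E_min`,
  `N = (E_max − E_min)/2`.  Defaults (LV): E_max 2.1, E_min 0.06 mmHg/mL,
  m1 1.32, m2 27.4, τ1 0.269 T, τ2 0.452 T; (LA): E_max 0.17, m2 13.1,
  τ1 0.110 T, τ2 0.18 T.  The formula is implemented literally: with these
  constants the LV curve peaks near 0.68 mmHg/mL, well below E_max — the
  printed normalization does not make the peak equal E_max and no
  renormalization is applied.  Calibration of the inflow and afterload
  absorbs the scale, so pressures remain physiologic.
- **Unloaded volumes** — V0 is not an observable here; defaults 10 mL (LV)
  and 5 mL (LA), configurable.
- **Atrial timing** — the LA elastance clock leads the LV clock by a
  configurable offset, default 0.12 T, so atrial contraction ends around
  the onset of ventricular systole.
- **Valves and coarctation** — forward conduits obey
  `ΔP = (2πρ/√E_L Co)·dQ/dt + ρ/(2 E_L Co²)·Q|Q|` with the energy-loss
  coefficient `E_L Co = EOA·A/(A − EOA)` (reference area A: ascending
  aorta for the aortic valve, LVOT for aortic regurgitation, downstream
  aorta for the coarctation).  The mitral side uses
  `ΔP = (M/EOA)·dQ/dt + ρ/(2 EOA²)·Q|Q|` with inertance M = 0.53 g/cm².
  `Q|Q|` rather than `Q²` keeps the convective term dissipative for
  reversed flow on the (signed) coarctation branch.
- **Diode logic** — each valve conduit integrates its inertial flow ODE
  while flow is positive or the opening gradient is favourable; when flow
  decelerates through zero the crossing is localized by bisection
  (to 10⁻⁶ s), the flow clamped at zero, and the conduit stays closed
  until the gradient reverses.  The element equations say nothing about
  opening/closing; this ideal-diode rule is the package's choice.
- **Energy-loss cap** — as EOA → A the coefficient diverges and the
  element's inertance vanishes, which only stiffens the ODE while the
  gradient is already physiologically zero; E_L Co is capped at 100 cm²
  (residual gradient < 0.01 mmHg at physiologic flows).
- **Pulmonary inflow** — rectified sine `Q_MPV·sin(πt/t_ee)` for
  t ≤ t_ee, zero for the rest of the cycle; per-beat volume
  2·Q_MPV·t_ee/π.
- **Bypass graft** — in the 0D circuit the graft is a Poiseuille
  resistance computed from its conduit geometry, `128 μL/(πD⁴)`.  A
  clinical-size graft (D ≈ 1.6 cm) is a near-short-circuit in these
  terms (~1.3·10⁻³ mmHg·s/mL); the 0D flow split between coarctation and
  graft therefore understates the coarctation share compared to a 3D
  computation, where junction losses dominate.  Only the upper-body vs
  descending split is calibrated, so this limitation does not affect the
  calibrated quantities.

### Integration

Implicit trapezoidal rule with damped fixed-point iteration (residual
tolerance 10⁻⁶, a step is rejected and halved when the iteration fails to
contract), adaptive step from 0.1 ms up to 3 ms with a local-error proxy
(trapezoid vs forward-Euler discrepancy, tolerance 5·10⁻⁴ relative),
states initialized to zero flows and configurable volumes/pressures.
Runs proceed cycle by cycle for up to 150 cycles; steady state is flagged
when SBP, DBP and stroke volume each drift < 0.1% between consecutive
cycles.  A typical moderate-COA patient reaches this in 25–40 cycles from
generic initial conditions and in a handful of cycles when warm-started.

Per-cycle summaries accumulate the integrals of all branch flows; the
steady-cycle metrics used by calibration are Aitken-extrapolated from the
last three cycles to remove the residual geometric drift (the slow mode is
total-blood-volume redistribution, decay ratio ≈ 0.85/cycle), giving
~0.05% effective accuracy at a 0.1% stopping tolerance.

## Calibration (`CoarctationModel.fit`)

Three sequential steps, iterated to joint convergence (max 5 outer loops;
each loop first re-verifies all targets with one simulation and re-runs
only the steps that are out of tolerance):

1. **Q_MPV** — secant root-find so the simulated forward LVOT stroke
   volume matches the Doppler value (tolerance 10⁻³ relative).  The map is
   nearly linear (per-beat volume conservation), so 2–4 simulations
   suffice.
2. **Systemic** — least squares so the steady-cycle aortic pressure
   extremes match the cuff pressures (each residual < 0.5 mmHg).
   *Identifiability:* the two compliances act nearly in parallel through
   the small R_ao, so (SBP, DBP) determine R_SA and the *total* compliance
   but not the C_ao:C_SAC split; a free 3-parameter fit wanders along this
   valley and is not reproducible run-to-run.  The fit therefore holds the
   ratio at its canonical initial proportion (0.5/2.0 = 0.25) and adjusts
   R_SA plus one common compliance scale — a well-posed 2×2 system whose
   solution is a deterministic function of the targets.  Every trial in
   the least squares starts from one frozen near-steady state so the
   residual function is smooth in the parameters.
3. **Flow split** — secant root-find on R_ub so the upper-body stroke
   volume matches the Doppler-derived arch-branch volume (post state:
   forward SV minus descending-aorta SV; pre state: 15% of forward SV),
   tolerance 0.5% relative.

Physical tolerances (0.5 mmHg on pressures, 10⁻³ on SV) are used instead
of a bare optimizer tolerance because they are testable and
solver-independent; the 10⁻⁶ figure is the inner ODE residual.

Round-trip recovery (the acceptance experiment) calibrates a synthetic
patient, simulates the calibrated circuit, synthesizes the record a
sonographer would measure on that virtual patient, recalibrates from the
canonical initial values, and compares all five parameters.  Because the
systemic fit is well-posed, recovery is limited only by solver and
steady-state-extraction tolerances.  What this does **not** show: that an
arbitrary (C_ao, C_SAC) pair off the canonical ratio could be recovered
from cuff pressures alone — it cannot, by the identifiability argument
above.

## The synthetic-patient generator

`generate_synthetic_patient(seed, severity, state)` draws one record from
envelopes typical of adult coarctation cohorts: heart rate 60–90 /min,
forward LVOT-SV 55–90 mL, SBP 120–160 / DBP 50–80 mmHg, ascending aorta
5–8 cm², LVOT 3–4.5 cm², descending-split fraction 0.55–0.75 of forward
flow (so the branch split can never exceed the forward volume), graft
length 6.9–8.3 cm and diameter 1.5–1.7 cm.  Severity maps to the
EOA/A ratio of the stenosis: none 1.0, mild 0.6, moderate 0.4,
severe 0.25, spanning peak gradients of roughly 0–14 mmHg.  VTIs are
derived from the drawn volumes so every record is internally consistent;
regurgitant orifices default to zero.  The generator emulates measurement
*envelopes*, not measurement noise or inter-observer variability — passing
tests demonstrate internal consistency of the pipeline, not accuracy
against real echocardiography.

## The lattice-Boltzmann kernel

D3Q19 (D2Q9 for fast and 2D cases), single-relaxation-time BGK.  The
Smagorinsky closure computes the non-equilibrium second moment
Π_ij = Σ c_i c_j (f − f_eq) per cell and solves
τ_eff² − τ0·τ_eff − 18 C_s²|Π|/ρ = 0 (filter width one cell,
|Π| = √(2Π:Π)), default C_s = 0.1; with C_s = 0 the operator is
bit-identical to plain BGK.  Body forces use the Guo scheme with the
half-force velocity shift.

Walls are defined by a signed distance function sampled at cell centers;
each fluid→solid link carries the fraction q from linear interpolation of
the SDF.  The interpolated bounce-back is

- q < 1/2:  `f_ᾱ(A) = 2q·f_α^c(A) + (1−2q)·f_α^c(A−c_α)`
- q ≥ 1/2:  `f_ᾱ(A) = 1/(2q)·f_α^c(A) + (2q−1)/(2q)·f_ᾱ^c(A)`

with plain bounce-back as fallback when the upstream neighbour is not
fluid; both branches coincide at q = 1/2 (tested bit-level against an
independent bounce-back implementation).  Wall normals come from the
gradient of the Gaussian-smoothed SDF.  Wall shear uses
ε_ij = −Π_ij/(2ρτc_s²), σ = 2με, traction σ·n projected tangentially;
isolated voxels with degenerate normals are skipped with a warning.

The velocity inlet writes equilibrium at the target velocity plus a
regularized off-equilibrium part built from second-order finite-difference
velocity gradients; inlet density is copied from the nearest bulk plane
(covering corners/edges).  Startup prepends a quarter-sine ramp from rest
to the waveform's initial value.  Outlets pin density to the reference
value with zero-gradient population copy; multiple outlets split the flow
by relative cross-sectional area.

**Units.** Diffusive scaling `dt = (ν_lattice/ν_phys)·dx²`; ν_lattice is
chosen to keep τ0 ∈ [0.51, 0.8] and the peak lattice velocity below ~0.1.

**Numerical accuracy.** With BGK and bounce-back-type walls the effective
wall position carries a small τ-dependent slip (observed
∝ (τ0 − 1/2)/h); the analytic suites therefore run at τ0 = 0.65, where
the plane-Poiseuille centerline error is ~0.5% at 44 cells across the gap
and the wall-shear error ~1.5% at 66 cells.  The oscillatory (Womersley)
amplitude at Wo = 3 agrees with the analytic series to better than 1%.
Mesh acceptance mirrors the usual protocol: a configuration passes when
peak velocity and pressure drop change by less than 2% between successive
1.5× refinements.

**Problem sizes.** The shipped suites use plane channels of 24–70 cells
across, tubes of radius 4–8 cells and constricted tubes of ~40–72 cells
length.  These desk-scale runs validate the kernel's operators; they are
three orders of magnitude below patient-scale aortic simulations and say
nothing about turbulence-resolving accuracy at clinical Reynolds numbers.

## Velocity-field comparison

Down-sampling is component-wise (tri)linear interpolation onto the coarse
grid; a coarse voxel is valid only if every contributing fine voxel is
valid.  Smoothing is penalized least squares in the DCT basis with the
smoothing parameter selected by generalized cross-validation; missing
voxels are imputed, and the robust mode pre-screens spikes against a 3³
local median (a pure residual criterion misses isolated outliers when GCV
selects a near-interpolating fit) before bisquare re-weighting.  The same
smoother applied to a down-sampled field serves as a proxy for the
smoothing inherent in phase-contrast velocimetry; no scanner point-spread
model is claimed.  Agreement statistics operate voxel-wise on velocity
magnitude by default (per-component available): bias = mean difference,
limits of agreement = 1.96 SD, Pearson r and R² = r².

The acceptance statistics use a constructed pair — a folded-normal speed
field (mean 0.9, SD 0.45 m/s, a realistic aortic spread) with differences
drawn N(−0.05, 0.098²) m/s — so the recovered bias (−0.05), LoA (0.192)
and R² (~0.95) are verified against the generating distribution, not
against clinical data.

## Known limitations

- The 0D model omits right-heart mechanics, baroreflex control and aortic
  wall compliance (rigid-wall assumption downstream of C_ao).
- Compliance split (C_ao vs C_SAC) is fixed by convention, not measured;
  only their combined effect on pulse pressure is calibrated.
- The 0D graft element ignores junction and curvature losses, so the 0D
  coarctation/graft split is indicative only.
- LBM runs are laminar-to-transitional desk benchmarks; LES behaviour is
  only verified to be inert where it should be (laminar resolved flow).
- The reference-cohort table contains internally inconsistent cells
  (flagged by `coaflow.cohort.check_derived_quantities`); the suite never
  forces a match to them.
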