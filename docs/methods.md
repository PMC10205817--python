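# Methods

## Model overview

`coasim` follows a rabbit model of coarctation of the aorta (CoA) through
four post-surgical time points (1, 3, 10, 20 weeks; "TP-1…TP-4"), for ten
study arms: a control plus three suture types (permanent `coa`, dissolvable
`dcoa`, rapidly dissolvable `rdcoa`) × three severities (wire diameters
2.6/2.0/1.6 mm ↔ peak-to-peak gradients ≤ 10, 10–20, ≥ 20 mmHg).  Because
the underlying animal measurements are not deposited, a calibrated
synthetic-cohort generator supplies the inputs, and a lumped (0D) compliant
network replaces 3D fluid–structure simulation for the hemodynamics.  The
chain per group and time point is:

1. generate a subject (measurements with the published group statistics);
2. process measurements into model inputs (cardiac output, outlet flow
   fractions, pressure summaries, Windkessel time constant, gradients);
3. back-project geometry and cardiac output to younger ages allometrically;
4. estimate and tune Windkessel outlets; tune regional wall moduli;
5. simulate the network to periodicity; extract mechanical stimuli
   (peak velocity, trans-coarctation gradient, radial strain, wall tension).

## Synthetic cohort: what it emulates, what it does not

The generator's defaults *are* the study conditions.  Group-level
calibration tables hold the published per-time-point cardiac output, mean
and pulse pressure, percent area obstruction, wall thickness, radial strain
and elastic moduli; a subject is these values plus configurable Gaussian
measurement noise (2 % on diameters and thickness, 2 mmHg on
Doppler-derived gradients, 0.5 mmHg on catheter pressures), a 10 %
systematic deficit on measured branch outflows (partial-volume-type error,
later repaired by diameter-proportional redistribution), and seeded
determinism (`numpy` Generator keyed by (seed, group)).

Specific generator choices:

- **Body weight** is anchored to the control cardiac-output ratios
  (CO ∝ W), with final-week weight 4.35 kg; a power-law fit provides
  continuous-time interpolation.  Heart rate uses a shallow power-law
  decline to 220 bpm at the final week (plausible rabbit values; the source
  data print none).
- **Geometry**: six stations (ascending −50 mm … descending +30 mm, arc
  length zero at the coarctation).  Final-week control diameters: ascending
  5.6 mm, proximal 8.0 mm (radius 4.0 mm), coarctation-site reference
  5.66 mm.  The proximal station follows its own growth anchors (radius
  2.7 mm at TP-1 → 4.0 mm at TP-4); other stations scale as W^(1/3).  These
  are documented calibrations chosen so the control wall-tension and
  peak-velocity baselines reproduce the published ~2500/~4000 dyn/cm and
  ~100 cm/s — not measurements.
- **Obstruction time course**: anchored *directly* to the published per-TP
  obstruction values (monotone PCHIP in time).  A mechanistic
  wire-plus-logistic model (`coarctation_timecourse`: lumen at the wire
  diameter, then logistic recovery toward a residual set by the final-week
  obstruction; onset 3 wk dissolvable / 1 wk rapid, rate 1.5 /wk) is
  retained for continuous-time what-if profiles, but it cannot pass through
  all four printed anchors — early obstructions exceed what the wire alone
  implies (peri-suture tissue response) and mid-study values lag the
  logistic.  Anchoring to the tables keeps the generator's obstruction
  exactly calibrated; the logistic stays the *model* of suture dissolution.
- **Doppler velocities** invert the gradient chain: a severity-dependent
  gradient target (7/15/28 mmHg at the initial obstruction, scaled by the
  squared relative obstruction as the suture dissolves) → transfer function
  → simplified Bernoulli → jet velocity, clamped at a 1 m/s transaortic
  baseline.
- **Pressure waveforms** are two-phase: cosine systolic upstroke/downstroke
  and a *pure exponential* diastolic decay with time constant τ (default
  0.8 s), the two free amplitudes solved linearly so the sampled cycle mean
  and max−min equal the requested MBP and PP exactly.  The pure exponential
  makes τ recoverable by log-linear regression, as the Windkessel
  estimation assumes.  Long τ at low PP makes the shape infeasible below a
  computable PP floor; the distal catheter synthesis clamps there.
- **Stress–strain curves** are exponential, σ = A(e^{Bε} − 1) with B = 5,
  A solved so the tangent modulus at the final-week operating strain equals
  the published modulus.

What the generator does *not* emulate: image data (it emits extracted
measurements only), inter-subject biological variability beyond measurement
noise (one representative subject per group, as the source analysis used),
collateral vessels, and arch curvature.  Passing tests therefore demonstrate
the *pipeline's* correctness under the published group conditions, not
robustness to real-cohort heterogeneity.

## Lumped network

Segments contribute Poiseuille resistance 8μl/(πr⁴), inertance ρl/A, and a
compliance from the linearized thin-wall tube law
A(P) = A_dia·(1 + (P−P_dia)·r/(Eh))², i.e. C_seg = 2·A_dia·L·r/(Eh), split
to the segment's end nodes.  Blood is Newtonian (ρ = 1.06 g/cm³,
μ = 4 cP).  The coarctation is a discrete element
ΔP = (8πμL_s/A_s²)·Q + K_t·(ρ/2)·(1/A_s − 1/A_0)²·Q|Q| with K_t = 1, whose
loss term equals the simplified Bernoulli gradient 4v² (v the jet-velocity
excess Q·(1/A_s − 1/A_0), in m/s, to within the 3.975 vs 4 conversion) —
the convention under which the severe-stenosis limit matches the clinical
Doppler relation.  Stenosis inertance is neglected.

Outlets are three-element Windkessels (R_c, C, R_d) at the arch node
(innominate, left carotid, left subclavian) and the distal descending node.
The network is a chain of 5 segments / 6 nodes mirroring the station
scaffold.

**Integration.** Backward Euler at dt = 0.2 ms (linear systems use a
prefactored LU; the stenosis nonlinearity uses Newton with analytic
Jacobian, residual tolerance 1e−4).  The state starts from the DC (steady)
solution, then a coarse-step startup sweep (10× dt, up to 60 cycles, sized
by the slowest outlet time constant) removes the slow capacitive transient
before the five graded cardiac cycles; the cycle-to-cycle mean-pressure
drift must end below 1 % (extra cycles are attempted, then an error is
raised).  With 5 cycles at ~273 ms (220 bpm) one control simulation takes
~0.1 s.

## Boundary-condition and wall tuning

Per outlet: R_tot = MBP/Q̄ (mean quantities are then exact at DC);
τ estimated from the proximal catheter trace (diastolic window from the
steepest pressure fall plus a 10 % margin to end diastole);
R_c = f·R_tot, R_d = (1−f)·R_tot, C = τ/R_d.

`tune_rc_fraction` implements the classical flow/MBP adjustment of the Rc
share within [0.05, 0.30].  Beyond it, `tune_pulse_pressure` matches the
simulated inlet pulse to the applied pulse pressure by searching the Rc
fraction (grid 0.02–0.30) and a common scale on the outlet compliances
(0.01–8, log-bisection between bracketing grid points) — the degree of
freedom that stands in for the distributed wall compliance of a 3D model.
PP(scale) is non-monotone once the stenosis pulse dominates, hence the
bracketing sweep rather than a pure bisection.  If no combination reaches
the target within 2 %, the closest within 15 % is accepted with a warning
and the misfit is visible in the report (`pp_sim` vs `pp`); the control
time points all tune to within 2 %.

Regional moduli start from the thin-wall relation E = PP·r/(ε·h) at the
applied pulse pressure and are then refined against the *simulated local*
pulse (up to 3 passes) until the realized station strain matches the
measured one within 3 % — the same iterative, strain-targeted modulus
tuning the source analysis used, needed because the chain amplifies the
pulse between inlet and coarctation.  The final-week material-curve tangent
is reported alongside; the thin-wall effective moduli reproduce the
published values only approximately (±15 %), the documented cost of a
closed-form tube law.

## Stimuli definitions

Per station: peak velocity = max |Q| over the adjacent segment (the
prescribed inflow at the inlet face) divided by the diastolic area; radial
strain = (P_sys − P_dia)·r/(Eh) from the tube law; systolic radius
r_sys = r_dia(1 + ε); normalized wall tension = P_sys [dyn/cm²] ×
(r_sys − r_dia) [cm].  The trans-coarctation gradient uses the standard
clinical peak-to-peak convention, max_t P_prox − max_t P_dist.  Systolic
(not instantaneous) pressure is reported in the tension, with the pressure
trace available for the alternative.  Unit conversions are fixed at
1 mmHg = 1333.22 dyn/cm².

## Numerical and interface choices

- Interpolation of diameter profiles is shape-preserving PCHIP (no
  overshoot below station minima); profile scaling to younger ages applies
  W^(1/3) with a cosine-blended coarctation override from the suture model.
- Severity bins: ≤ 10 → `le10`, open interval → `10to20`, ≥ 20 → `ge20`.
- Negative transfer-function outputs clamp to zero with a warning.
- The obstruction-based pulse-pressure regression pools all groups'
  final-week pairs by default (configurable); the pipeline applies the
  published per-TP pulse pressures directly as pressure targets.
- Optional STL export writes a capped surface of revolution along a
  straight centerline (mm units); cross-sections match the profile to
  < 0.5 % at 64 ring points.
- Problem sizes: tests and the acceptance script simulate the control group
  (4 time points, ~1360 steps/cycle × 5 cycles each, plus tuning sweeps of
  ~10–30 simulations per time point) — about 10 s end to end; the full
  10-group study is ~10 minutes and is exercised via the CLI/examples
  rather than the default test run.

## Known limitations

- Single-path 0D chain: no collateral circulation, so severe untreated
  groups overestimate the trans-coarctation gradient and inlet mean
  pressure relative to measured values (mean pressure is matched at the
  outlets); severity comparisons are ordinal, not absolute.
- No wave propagation (0D, not 1D characteristics): pulse amplification is
  lumped, wave reflection timing is not resolved.
- Wall shear stress is out of scope, as in the source analysis.
- The thin-wall, linearized strain↔modulus coupling trades exactness of the
  published moduli for an exact strain round trip.
- Some treated-group time points cannot reach their published pulse
  pressure under the fixed half-sine inflow (peak-to-mean 4); they are
  flagged and reported at the closest achievable pulse.
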