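# coasim

Reduced-order longitudinal hemodynamics of coarctation of the aorta (CoA).

Coarctation — a congenital narrowing of the thoracic aorta — is usually
repaired against a clinical threshold of a 20 mmHg peak-to-peak blood
pressure gradient (BPG_pp), yet treated patients often remain hypertensive.
The mechanistic suspects are the *mechanical stimuli* the proximal aorta
experiences while the narrowing is present: elevated wall tension, altered
radial strain, and jet-dominated velocity patterns.  Preclinical work
quantifies these stimuli longitudinally in rabbits with surgically induced
CoA of graded severity (suture tied against 2.6 / 2.0 / 1.6 mm wires →
BPG_pp ≤ 10, 10–20, ≥ 20 mmHg) and graded duration (permanent, dissolvable,
rapidly dissolvable sutures), with measurements at ~1, 3, 10 and 20 weeks
post-surgery (TP-1…TP-4).

`coasim` is a tested Python implementation of that analysis chain for
modelers and experimentalists who want to exercise it end to end at desk
scale, with the 3D fluid–structure simulations replaced by a lumped
(0D) compliant network:

- **synthetic cohort** (`coasim.cohort`) — seeded subjects whose
  longitudinal body weight, station diameters, Doppler velocities, catheter
  waveforms, branch flows, wall thickness and uniaxial stress–strain curves
  carry the published group statistics (10 groups × 4 time points);
- **measurement processing** (`coasim.measurements`) — cardiac output by
  cycle integration, MBP/PP extraction, subclavian estimation by sagittal
  symmetry, diameter-proportional redistribution of the branch-flow mass
  defect, the simplified Bernoulli gradient ΔP = 4v², the Doppler-to-catheter
  transfer function PIDG = 1.76·PIBPG − 6.9, severity classification, and the
  obstruction-based pulse-pressure regression;
- **allometry** (`coasim.allometry`) — log-space power-law fits, weight-based
  back-projection (CO ∝ W, diameters ∝ W^(1/3)) and a rabbit-to-human age map;
- **boundary conditions** (`coasim.windkessel`) — three-element Windkessel
  estimation (τ = R_d·C from the diastolic decay, C = −t/(R_d ln(P/P₀)),
  R_tot = MBP/Q̄) and iterative tuning against the network simulation;
- **geometry & wall mechanics** (`coasim.geometry`) — shape-preserving
  diameter profiles, obstruction % = (1 − (d/d_ref)²)·100, radial strain,
  tangent moduli of hyperelastic curves, the thin-wall strain↔modulus
  relation E = PP·r/(ε·h), and normalized wall tension
  T = P·Δr (dyn/cm);
- **lumped solver** (`coasim.rom`) — compliant segments (thin-wall tube law),
  a stenosis element with viscous + Borda–Carnot loss (severe-stenosis limit
  = simplified Bernoulli), RCR outlets, implicit stepping at 0.2 ms for five
  cardiac cycles to periodicity;
- **pipeline** (`coasim.pipeline`) — generate → process → fit → tune →
  simulate → report for any subset of the 10 groups (40 simulated time
  points for the full study), plus a thin `coasim` CLI.

## Worked example

```bash
python examples/05_control_pipeline.py
```

runs the control group through the whole chain and prints:

```
TP  PP_sim  v_asc   strain  tension   P_sys
     mmHg   cm/s      %     dyn/cm    mmHg
1    14.7    69.4    10.8     2576    65.6
2    14.6    76.6    11.2     3035    64.9
3    15.0    94.8    12.2     3736    63.7
4    14.8   103.6    11.8     3988    63.3
```

Reading: the tuned outlets reproduce the applied pulse pressure (14.9 mmHg)
within a few percent at every age; the final-week peak ascending-aortic
velocity is ~100 cm/s; proximal radial strain stays near the measured
11–12 %; and proximal wall tension — systolic pressure times the radial
displacement beyond diastole — climbs from ~2500 dyn/cm at TP-1 to
~4000 dyn/cm at TP-4, the control baseline against which coarctation-induced
stimuli are judged.  The other examples cover the cohort generator, the
gradient/transfer chain, Windkessel estimation, allometric scaling and the
severity ordering of the trans-coarctation gradient.

The full study (all 10 groups) runs from the shell:

```bash
coasim run-all --seed 1 --out coasim_out     # ~10 min, writes CSV/JSON per group
```

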