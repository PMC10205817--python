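"""Seeded synthetic cohort generator.

The study this package emulates followed rabbits with surgically induced
coarctation of the aorta (CoA): three suture types (permanent, dissolvable,
rapidly dissolvable) crossed with three severities (wire diameters 2.6, 2.0,
1.6 mm producing peak-to-peak gradients <= 10, 10-20, >= 20 mmHg), plus a
control group, measured at ~1, 3, 10 and 20 weeks post-surgery (TP-1..TP-4).
No raw data are deposited, so this module generates subjects whose
longitudinal measurements carry the statistical and temporal structure the
downstream analysis assumes, calibrated to the published group tables
(cardiac output, blood pressures, obstruction %, wall thickness, radial
strain and elastic moduli).

The calibration tables below ARE the study conditions; they are inputs to
the generator, not fitted quantities.  Per-timepoint obstruction is anchored
directly to the printed values (a monotone interpolant in time per group),
because a mechanistic wire/logistic suture model cannot pass through all
four printed anchors at once (the printed obstructions early on exceed what
the wire alone would produce, reflecting peri-suture tissue response).  The
mechanistic model remains available as :func:`coarctation_timecourse` for
continuous-time what-if profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .waveform import Waveform, generate_pressure_waveform

__all__ = [
    "TIMEPOINTS_WEEKS",
    "GROUP_NAMES",
    "StudyGroup",
    "StressStrainCurve",
    "SubjectRecord",
    "CohortConfig",
    "group_calibration",
    "coarctation_timecourse",
    "generate_subject",
    "generate_material_curve",
    "write_cohort_csv",
]

#: Study time points, weeks post-surgery.
TIMEPOINTS_WEEKS = (1.0, 3.0, 10.0, 20.0)

_WIRE_BY_SEVERITY = {"le10": 2.6, "10to20": 2.0, "ge20": 1.6}
_SEVERITY_BY_WIRE = {v: k for k, v in _WIRE_BY_SEVERITY.items()}
_SUTURES = ("permanent", "dissolvable", "rapid")

#: Dissolution onset (weeks) per suture type; permanent sutures never dissolve.
DISSOLUTION_ONSET_WK = {"dissolvable": 3.0, "rapid": 1.0}
#: Logistic recovery rate, 1/week.
DISSOLUTION_RATE = 1.5


@dataclass(frozen=True)
class StudyGroup:
    """One experimental arm: suture type x severity.

    The wire diameter and severity label are a fixed bijection
    (2.6 mm <-> le10, 2.0 <-> 10to20, 1.6 <-> ge20); `control` subjects
    carry suture=None.
    """

    suture: str | None
    wire_diameter_mm: float | None
    severity_label: str | None

    def __post_init__(self) -> None:
        if self.suture is None:
            if self.wire_diameter_mm is not None or self.severity_label is not None:
                raise ValueError("control group carries no wire or severity")
            return
        if self.suture not in _SUTURES:
            raise ValueError(f"unknown suture type {self.suture!r}")
        if _SEVERITY_BY_WIRE.get(self.wire_diameter_mm) != self.severity_label:
            raise ValueError("wire diameter and severity label must correspond")

    @property
    def is_control(self) -> bool:
        return self.suture is None

    @property
    def name(self) -> str:
        if self.is_control:
            return "control"
        prefix = {"permanent": "coa", "dissolvable": "dcoa", "rapid": "rdcoa"}[self.suture]
        return f"{prefix}_{self.severity_label}"

    @classmethod
    def from_name(cls, name: str) -> "StudyGroup":
        if name == "control":
            return cls(None, None, None)
        for prefix, suture in (("rdcoa", "rapid"), ("dcoa", "dissolvable"), ("coa", "permanent")):
            if name.startswith(prefix + "_"):
                sev = name[len(prefix) + 1 :]
                if sev in _WIRE_BY_SEVERITY:
                    return cls(suture, _WIRE_BY_SEVERITY[sev], sev)
        raise ValueError(f"unknown group name {name!r}")


def make_group(suture: str | None, severity: str | None = None) -> StudyGroup:
    """Convenience constructor from suture type and severity label."""
    if suture is None:
        return StudyGroup(None, None, None)
    return StudyGroup(suture, _WIRE_BY_SEVERITY[severity], severity)


# --------------------------------------------------------------------------
# Group calibration (published group tables; values per TP-1..TP-4)
# --------------------------------------------------------------------------

_CAL = {
    # name: co (ml/s), mbp (mmHg), pp (mmHg), obstruction (%),
    #       h_prox / h_dist (mm), strain prox/coa/dist (%), E prox/dist (kPa)
    "control": dict(
        co=(2.13, 2.58, 4.76, 6.18), mbp=55.7, pp=(14.9, 14.9, 14.9, 14.9),
        obstruction=(0, 0, 0, 0),
        h_prox=(0.29, 0.31, 0.33, 0.35), h_dist=(0.29, 0.31, 0.33, 0.35),
        strain_prox=(11, 11, 12, 12), strain_coa=(11, 11, 12, 12),
        strain_dist=(11, 11, 12, 12),
        e_prox=(190, 200, 220, 220), e_dist=(190, 200, 220, 220),
    ),
    "coa_le10": dict(
        co=(2.20, 2.53, 3.97, 5.23), mbp=71.5, pp=(17.0, 17.2, 18.3, 19.5),
        obstruction=(69, 71, 76, 80),
        h_prox=(0.33, 0.34, 0.35, 0.37), h_dist=(0.34, 0.34, 0.34, 0.34),
        strain_prox=(10, 10, 11, 11), strain_coa=(0, 0, 0, 0),
        strain_dist=(11, 10, 9, 7),
        e_prox=(130, 140, 180, 180), e_dist=(130, 130, 100, 100),
    ),
    "coa_10to20": dict(
        co=(1.91, 2.25, 3.98, 5.98), mbp=66.7, pp=(16.5, 16.9, 22.2, 24.3),
        obstruction=(63, 68, 85, 87),
        h_prox=(0.29, 0.32, 0.34, 0.35), h_dist=(0.32, 0.32, 0.32, 0.32),
        strain_prox=(13, 12, 10, 10), strain_coa=(0, 0, 0, 0),
        strain_dist=(10, 9, 5, 4),
        e_prox=(140, 150, 220, 260), e_dist=(120, 120, 110, 90),
    ),
    "coa_ge20": dict(
        co=(2.57, 2.87, 4.64, 6.21), mbp=70.2, pp=(24.2, 24.9, 28.2, 30.2),
        obstruction=(87, 88, 90, 92),
        h_prox=(0.32, 0.33, 0.37, 0.40), h_dist=(0.34, 0.33, 0.30, 0.28),
        strain_prox=(12, 12, 12, 10), strain_coa=(0, 0, 0, 0),
        strain_dist=(5, 5, 5, 6),
        e_prox=(230, 260, 310, 350), e_dist=(220, 160, 150, 90),
    ),
    "dcoa_le10": dict(
        co=(2.47, 2.78, 4.73, 7.02), mbp=63.3, pp=(16.9, 16.8, 15.9, 15.6),
        obstruction=(68, 67, 45, 34),
        h_prox=(0.35, 0.36, 0.38, 0.39), h_dist=(0.33, 0.32, 0.29, 0.28),
        strain_prox=(14, 14, 10, 9), strain_coa=(0, 0, 13, 13),
        strain_dist=(13, 13, 11, 10),
        e_prox=(290, 300, 330, 480), e_dist=(250, 260, 320, 450),
    ),
    "dcoa_10to20": dict(
        co=(1.61, 2.07, 4.29, 6.64), mbp=65.2, pp=(18.8, 18.5, 16.0, 15.7),
        obstruction=(78, 77, 50, 40),
        h_prox=(0.31, 0.33, 0.39, 0.43), h_dist=(0.38, 0.37, 0.33, 0.28),
        strain_prox=(10, 10, 9, 8), strain_coa=(0, 0, 12, 12),
        strain_dist=(8, 8, 8, 7),
        e_prox=(200, 210, 340, 420), e_dist=(200, 200, 340, 420),
    ),
    "dcoa_ge20": dict(
        co=(2.55, 2.90, 5.00, 6.96), mbp=66.4, pp=(26.4, 28.8, 20.6, 15.9),
        obstruction=(89, 91, 82, 47),
        h_prox=(0.29, 0.30, 0.32, 0.34), h_dist=(0.32, 0.31, 0.29, 0.28),
        strain_prox=(15, 14, 11, 11), strain_coa=(0, 0, 12, 14),
        strain_dist=(4, 4, 4, 3),
        e_prox=(230, 260, 280, 290), e_dist=(170, 180, 180, 210),
    ),
    "rdcoa_le10": dict(
        co=(3.60, 4.14, 6.94, 8.95), mbp=60.4, pp=(16.0, 15.8, 15.3, 15.0),
        obstruction=(51, 45, 19, 5),
        h_prox=(0.31, 0.32, 0.33, 0.33), h_dist=(0.34, 0.33, 0.31, 0.30),
        strain_prox=(11, 9, 8, 8), strain_coa=(0, 4, 7, 8),
        strain_dist=(8, 8, 7, 7),
        e_prox=(290, 370, 460, 540), e_dist=(290, 360, 450, 540),
    ),
    "rdcoa_10to20": dict(
        co=(2.44, 3.05, 5.93, 8.19), mbp=63.8, pp=(16.8, 15.8, 15.3, 15.3),
        obstruction=(66, 44, 20, 19),
        h_prox=(0.31, 0.32, 0.33, 0.34), h_dist=(0.35, 0.34, 0.33, 0.32),
        strain_prox=(11, 10, 9, 8), strain_coa=(0, 8, 11, 11),
        strain_dist=(8, 9, 8, 8),
        e_prox=(150, 230, 260, 270), e_dist=(150, 220, 240, 240),
    ),
    "rdcoa_ge20": dict(
        co=(2.95, 3.46, 6.32, 8.46), mbp=56.9, pp=(21.0, 21.8, 15.6, 15.6),
        obstruction=(83, 84, 33, 33),
        h_prox=(0.31, 0.32, 0.36, 0.38), h_dist=(0.33, 0.34, 0.34, 0.34),
        strain_prox=(10, 10, 8, 7), strain_coa=(0, 4, 6, 5),
        strain_dist=(4, 5, 6, 6),
        e_prox=(280, 280, 350, 400), e_dist=(280, 280, 350, 400),
    ),
}

GROUP_NAMES = tuple(_CAL)

#: Final-week body weight, kg (controls and groups alike).
W4_KG = 4.35
#: Reference (unobstructed) diameter at the coarctation site at TP-4, mm.
D_REF_COA_TP4_MM = 5.66
#: Control station scaffold at TP-4: arc length (mm, 0 at coarctation) and
#: diastolic diameter (mm).  Proximal diameter anchors are 5.4 mm (TP-1) to
#: 8.0 mm (TP-4) per the package calibration (radii 2.7 -> 4.0 mm).
STATIONS = ("ascending", "arch", "proximal", "coa", "distal", "descending")
STATION_S_MM = {"ascending": -50.0, "arch": -30.0, "proximal": -12.0,
                "coa": 0.0, "distal": 12.0, "descending": 30.0}
_STATION_D4_MM = {"ascending": 5.6, "arch": 6.8, "proximal": 8.0,
                  "coa": D_REF_COA_TP4_MM, "distal": 7.6, "descending": 7.0}
#: Proximal diameter growth exponent vs time (weeks): anchors 5.4 mm @ 1 wk,
#: 8.0 mm @ 20 wk.
_PROX_GROWTH_EXP = float(np.log(8.0 / 5.4) / np.log(20.0))

#: Severity-group peak-to-peak gradient targets at full obstruction, mmHg.
BPG_TARGET_MMHG = {"le10": 7.0, "10to20": 15.0, "ge20": 28.0}

#: Outlet branch flow fractions of cardiac output at TP-4.
BRANCH_FRACTIONS = {"innominate": 0.18, "left_carotid": 0.08,
                    "left_subclavian": 0.10, "descending": 0.64}
#: Right carotid fraction (sub-branch of the innominate; measured separately).
RIGHT_CAROTID_FRACTION = 0.08
#: Outlet diameters (mm) used for diameter-proportional flow redistribution.
BRANCH_DIAMETERS_MM = {"innominate": 2.2, "left_carotid": 1.5,
                       "left_subclavian": 1.5, "descending": 4.5}


def group_calibration(group: StudyGroup | str) -> dict:
    """Return the calibration record (published table values) for a group."""
    name = group if isinstance(group, str) else group.name
    try:
        return dict(_CAL[name])
    except KeyError:
        raise ValueError(f"unknown group {name!r}") from None


def body_weights_kg(w4: float = W4_KG) -> np.ndarray:
    """Per-TP body weights: proportional to the control cardiac output anchors.

    Cardiac output is proportional to body weight, so the weight time course
    is anchored to the control CO ratios and the final-week weight.
    """
    co = np.asarray(_CAL["control"]["co"], dtype=float)
    return w4 * co / co[-1]


def heart_rate_bpm(t_weeks: float, hr_tp4: float = 220.0, exponent: float = -0.06) -> float:
    """Heart rate vs age: shallow power-law decline, anchored at TP-4."""
    if t_weeks <= 0:
        raise ValueError("time must be positive")
    return hr_tp4 * (t_weeks / TIMEPOINTS_WEEKS[-1]) ** exponent


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class StressStrainCurve:
    """Sampled uniaxial stress-strain curve through the origin.

    If generated parametrically the exponential coefficients (A, B) of
    sigma = A*(exp(B*eps) - 1) are retained for analytic tangents.
    """

    strain: np.ndarray
    stress_kpa: np.ndarray
    coef_a: float | None = None
    coef_b: float | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_kpa = np.asarray(self.stress_kpa, dtype=float)
        if self.strain.size < 2 or self.strain.size != self.stress_kpa.size:
            raise ValueError("need matching strain/stress samples")
        if np.any(np.diff(self.strain) <= 0):
            raise ValueError("strain must be strictly increasing")
        if np.any(np.diff(self.stress_kpa) < 0):
            raise ValueError("stress must be non-decreasing")
        if abs(self.strain[0]) > 1e-12 or abs(self.stress_kpa[0]) > 1e-9:
            raise ValueError("curve must pass through (0, 0)")


def generate_material_curve(
    e_target_kpa: float,
    strain_op: float,
    coef_b: float = 5.0,
    max_strain: float = 0.4,
    n_samples: int = 81,
) -> StressStrainCurve:
    """Exponential stress-strain curve with a prescribed tangent modulus.

    sigma = A*(exp(B*eps) - 1) with A solved so d sigma/d eps at the
    operating strain equals ``e_target_kpa``; B -> 0 degenerates to the
    linear curve sigma = E*eps.
    """
    if e_target_kpa <= 0:
        raise ValueError("target modulus must be positive")
    if not 0 <= strain_op < 0.5:
        raise ValueError("operating strain must be in [0, 0.5)")
    strain = np.linspace(0.0, max_strain, n_samples)
    if abs(coef_b) < 1e-9:
        return StressStrainCurve(strain, e_target_kpa * strain, coef_a=None, coef_b=0.0)
    coef_a = e_target_kpa / (coef_b * np.exp(coef_b * strain_op))
    stress = coef_a * (np.exp(coef_b * strain) - 1.0)
    return StressStrainCurve(strain, stress, coef_a=float(coef_a), coef_b=float(coef_b))


@dataclass
class SubjectRecord:
    """One synthetic subject's longitudinal measurements across 4 time points."""

    group: StudyGroup
    seed: int
    timepoints_weeks: tuple[float, ...]
    body_weight_kg: np.ndarray
    heart_rate_bpm: np.ndarray
    #: per-TP: station -> (diastolic mm, systolic mm)
    station_diameters: list[dict[str, tuple[float, float]]]
    #: per-TP (proximal, distal) wall thickness, mm
    wall_thickness_mm: list[tuple[float, float]]
    doppler_peak_velocity_m_s: np.ndarray
    #: (proximal, distal) catheter pressure waveforms at TP-4
    catheter_waveforms: tuple[Waveform, Waveform]
    #: measured mean branch flows at TP-4, ml/s (with mass-conservation error)
    branch_mean_flows_ml_s: dict[str, float]
    #: (proximal, distal) uniaxial curves from final-week material testing
    material_curves: tuple[StressStrainCurve, StressStrainCurve]
    obstruction_pct: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def validate(self) -> None:
        if np.any(np.diff(self.body_weight_kg) <= 0):
            raise ValueError("body weight must be strictly increasing")
        for per_tp in self.station_diameters:
            for dia, sys in per_tp.values():
                if dia <= 0 or sys < dia:
                    raise ValueError("station diameters must satisfy 0 < dia <= sys")
        for h_p, h_d in self.wall_thickness_mm:
            if h_p <= 0 or h_d <= 0:
                raise ValueError("thickness must be positive")


@dataclass
class CohortConfig:
    """Generator noise levels and calibration overrides.

    noise_scale multiplies every noise sigma (0 reproduces the calibration
    exactly); the mass_error fraction is the systematic deficit of summed
    measured branch outflows relative to the inflow (partial-volume-type
    underestimation, redistributed downstream by the processing step).
    """

    noise_diameter_frac: float = 0.02
    noise_gradient_mmhg: float = 2.0
    noise_bp_mmhg: float = 0.5
    noise_thickness_frac: float = 0.02
    noise_flow_frac: float = 0.02
    mass_error: float = 0.10
    noise_scale: float = 1.0
    tau_s: float = 0.8
    w4_kg: float = W4_KG
    hr_tp4_bpm: float = 220.0
    material_coef_b: float = 5.0
    doppler_baseline_m_s: float = 1.0
    samples_per_cycle: int = 1000

    def __post_init__(self) -> None:
        for name in ("noise_diameter_frac", "noise_gradient_mmhg", "noise_bp_mmhg",
                     "noise_thickness_frac", "noise_flow_frac", "mass_error", "noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# --------------------------------------------------------------------------
# Coarctation time course
# --------------------------------------------------------------------------


def coarctation_timecourse(group: StudyGroup, t_weeks: float, d_ref_mm: float) -> float:
    """Mechanistic coarctation inner diameter (mm) at time t.

    Permanent sutures hold the lumen at the wire diameter indefinitely.
    Dissolvable sutures recover logistically toward a residual diameter
    after the dissolution onset: d(t) = d_wire + (d_res - d_wire) /
    (1 + exp(-k (t - t0))), with onset t0 = 3 wk (dissolvable) or 1 wk
    (rapid) and rate k = 1.5 /wk.  The residual diameter corresponds to the
    group's published final-week obstruction relative to ``d_ref_mm``.

    Controls return the reference diameter unchanged (0 % obstruction).
    """
    if t_weeks < 0:
        raise ValueError("time must be >= 0")
    if group.is_control:
        return d_ref_mm
    if d_ref_mm <= group.wire_diameter_mm:
        raise ValueError("reference diameter must exceed the wire diameter")
    if group.suture == "permanent":
        return group.wire_diameter_mm
    o_res = group_calibration(group)["obstruction"][-1] / 100.0
    d_res = d_ref_mm * float(np.sqrt(1.0 - o_res))
    t0 = DISSOLUTION_ONSET_WK[group.suture]
    sigma = 1.0 / (1.0 + np.exp(-DISSOLUTION_RATE * (t_weeks - t0)))
    return float(group.wire_diameter_mm + (d_res - group.wire_diameter_mm) * sigma)


def obstruction_timecourse(group: StudyGroup | str, t_weeks) -> np.ndarray:
    """Calibrated percent area obstruction vs time (weeks).

    Monotone piecewise-cubic interpolation through the published per-TP
    anchors, held flat outside the studied window.  This is the generator's
    authoritative obstruction course (see module docstring).
    """
    anchors = np.asarray(group_calibration(group)["obstruction"], dtype=float)
    t = np.atleast_1d(np.asarray(t_weeks, dtype=float))
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    interp = PchipInterpolator(TIMEPOINTS_WEEKS, anchors, extrapolate=False)
    out = interp(np.clip(t, TIMEPOINTS_WEEKS[0], TIMEPOINTS_WEEKS[-1]))
    return out if np.ndim(t_weeks) else float(out[0])


# --------------------------------------------------------------------------
# Subject generation
# --------------------------------------------------------------------------


def _growth_factor(tp_index: int, config: CohortConfig) -> float:
    """Diameter growth factor (w/w4)^(1/3) at a study time point."""
    w = body_weights_kg(config.w4_kg)
    return float((w[tp_index] / w[-1]) ** (1.0 / 3.0))


def station_reference_diameters(tp_index: int, config: CohortConfig | None = None) -> dict[str, float]:
    """Noise-free diastolic station diameters (mm) of the reference aorta.

    The proximal station follows its own calibrated growth anchors (radius
    2.7 mm at TP-1 to 4.0 mm at TP-4); all other stations scale
    geometrically with body weight (exponent 1/3).
    """
    config = config or CohortConfig()
    t = TIMEPOINTS_WEEKS[tp_index]
    gf = _growth_factor(tp_index, config)
    out = {}
    for st, d4 in _STATION_D4_MM.items():
        if st == "proximal":
            out[st] = 5.4 * (t / TIMEPOINTS_WEEKS[0]) ** _PROX_GROWTH_EXP
        else:
            out[st] = d4 * gf
    return out


def group_bpg_pp(group: StudyGroup | str, tp_index: int) -> float:
    """Calibrated peak-to-peak gradient target (mmHg) for a group/TP.

    The severity target applies at the initial obstruction level and scales
    with the square of the relative obstruction as the suture dissolves
    (a jet-velocity-like dependence on residual narrowing).
    """
    g = StudyGroup.from_name(group) if isinstance(group, str) else group
    if g.is_control:
        return 0.0
    obs = group_calibration(g)["obstruction"]
    base = BPG_TARGET_MMHG[g.severity_label]
    return base * (obs[tp_index] / obs[0]) ** 2


def _doppler_velocity(bpg_pp: float, config: CohortConfig, noise: float) -> float:
    """Peak Doppler velocity (m/s) consistent with a target gradient.

    Inverts the gradient chain: the peak-to-peak target plays the role of
    the catheter PIBPG, the transfer function gives the Doppler PIDG, and
    the simplified Bernoulli equation gives the jet velocity; clamped at a
    baseline transaortic velocity for unobstructed flow.
    """
    from .measurements import TRANSFER_INTERCEPT, TRANSFER_SLOPE

    pidg = TRANSFER_SLOPE * bpg_pp + TRANSFER_INTERCEPT + noise
    v = float(np.sqrt(max(pidg, 0.0) / 4.0))
    return max(v, config.doppler_baseline_m_s)


def _distal_pressure_targets(
    mbp_prox: float, pp_prox: float, bpg_pp: float, hr: float, config: CohortConfig
) -> tuple[float, float]:
    """(MBP, PP) of the distal catheter so peak systolic pressures differ by bpg_pp."""
    from .waveform import pressure_shape_coefficients

    mbp_dist = mbp_prox - 0.25 * bpg_pp
    shape = pressure_shape_coefficients(hr, config.tau_s,
                                        samples_per_cycle=config.samples_per_cycle)
    # systolic peak is linear in (MBP, PP) for the fixed waveform shape
    sys_prox = shape["alpha"] * mbp_prox + shape["beta"] * pp_prox
    target_sys = sys_prox - bpg_pp
    pp_dist = (target_sys - shape["alpha"] * mbp_dist) / shape["beta"]
    pp_dist = max(pp_dist, 1.02 * shape["pp_min_frac"] * mbp_dist)
    return mbp_dist, pp_dist


def generate_subject(
    group: StudyGroup | str, seed: int, config: CohortConfig | None = None
) -> SubjectRecord:
    """Generate one synthetic subject (deterministic for a fixed seed)."""
    g = StudyGroup.from_name(group) if isinstance(group, str) else group
    cal = group_calibration(g)
    config = config or CohortConfig()
    group_index = GROUP_NAMES.index(g.name)
    rng = np.random.default_rng([int(seed), group_index])
    ns = config.noise_scale

    weights = body_weights_kg(config.w4_kg)
    hrs = np.array([heart_rate_bpm(t, config.hr_tp4_bpm) for t in TIMEPOINTS_WEEKS])

    station_diameters: list[dict[str, tuple[float, float]]] = []
    obstruction = np.asarray(cal["obstruction"], dtype=float)
    for k in range(4):
        ref = station_reference_diameters(k, config)
        per_tp: dict[str, tuple[float, float]] = {}
        for st in STATIONS:
            d_dia = ref[st]
            if st == "coa":
                d_dia = d_dia * float(np.sqrt(1.0 - obstruction[k] / 100.0))
                strain = cal["strain_coa"][k]
            elif st in ("distal", "descending"):
                strain = cal["strain_dist"][k]
            else:
                strain = cal["strain_prox"][k]
            z = rng.normal()
            noise_factor = 1.0 + ns * config.noise_diameter_frac * z
            d_dia = max(d_dia * noise_factor, 0.1)
            d_sys = d_dia * (1.0 + strain / 100.0)
            per_tp[st] = (d_dia, d_sys)
        station_diameters.append(per_tp)

    wall_thickness = []
    for k in range(4):
        zp, zd = rng.normal(size=2)
        wall_thickness.append((
            cal["h_prox"][k] * (1.0 + ns * config.noise_thickness_frac * zp),
            cal["h_dist"][k] * (1.0 + ns * config.noise_thickness_frac * zd),
        ))

    doppler = np.array([
        _doppler_velocity(group_bpg_pp(g, k), config,
                          ns * config.noise_gradient_mmhg * rng.normal())
        for k in range(4)
    ])

    hr4 = float(hrs[-1])
    mbp4 = cal["mbp"] + ns * config.noise_bp_mmhg * rng.normal()
    pp4 = max(cal["pp"][-1] + ns * config.noise_bp_mmhg * rng.normal(), 1.0)
    prox_wave = generate_pressure_waveform(mbp4, pp4, hr4, config.tau_s,
                                           samples_per_cycle=config.samples_per_cycle)
    mbp_d, pp_d = _distal_pressure_targets(mbp4, pp4, group_bpg_pp(g, 3), hr4, config)
    dist_wave = generate_pressure_waveform(mbp_d, pp_d, hr4, config.tau_s,
                                           samples_per_cycle=config.samples_per_cycle)

    co4 = cal["co"][-1]
    deficit = 1.0 - config.mass_error
    flows = {}
    for branch, frac in BRANCH_FRACTIONS.items():
        if branch == "left_subclavian":
            continue  # not measured directly; estimated from the innominate
        z = rng.normal()
        flows[branch] = co4 * frac * deficit * (1.0 + ns * config.noise_flow_frac * z)
    # the right carotid is a sub-branch of the innominate; its measurement
    # feeds the symmetric subclavian estimate downstream
    flows["right_carotid"] = co4 * RIGHT_CAROTID_FRACTION * deficit * (
        1.0 + ns * config.noise_flow_frac * rng.normal()
    )
    flows["ascending"] = co4

    strain_op = cal["strain_prox"][-1] / 100.0
    curves = (
        generate_material_curve(cal["e_prox"][-1], strain_op, config.material_coef_b),
        generate_material_curve(cal["e_dist"][-1], cal["strain_dist"][-1] / 100.0,
                                config.material_coef_b),
    )

    record = SubjectRecord(
        group=g,
        seed=int(seed),
        timepoints_weeks=TIMEPOINTS_WEEKS,
        body_weight_kg=weights,
        heart_rate_bpm=hrs,
        station_diameters=station_diameters,
        wall_thickness_mm=wall_thickness,
        doppler_peak_velocity_m_s=doppler,
        catheter_waveforms=(prox_wave, dist_wave),
        branch_mean_flows_ml_s=flows,
        material_curves=curves,
        obstruction_pct=obstruction,
    )
    record.validate()
    return record


# --------------------------------------------------------------------------
# External interfaces
# --------------------------------------------------------------------------


def cohort_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject x time point x station (documented column schema)."""
    rows = []
    for i, rec in enumerate(records):
        for k, t in enumerate(rec.timepoints_weeks):
            for st in STATIONS:
                dia, sys = rec.station_diameters[k][st]
                rows.append({
                    "subject": i,
                    "group": rec.group.name,
                    "seed": rec.seed,
                    "tp": k + 1,
                    "t_weeks": t,
                    "body_weight_kg": rec.body_weight_kg[k],
                    "heart_rate_bpm": rec.heart_rate_bpm[k],
                    "station": st,
                    "s_mm": STATION_S_MM[st],
                    "d_dia_mm": dia,
                    "d_sys_mm": sys,
                    "h_prox_mm": rec.wall_thickness_mm[k][0],
                    "h_dist_mm": rec.wall_thickness_mm[k][1],
                    "doppler_v_m_s": rec.doppler_peak_velocity_m_s[k],
                    "obstruction_pct": rec.obstruction_pct[k],
                })
    return pd.DataFrame(rows)


def write_cohort_csv(records: list[SubjectRecord], out_dir: str | Path) -> tuple[Path, Path]:
    """Write the cohort table (CSV) and metadata (JSON); returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "cohort.csv"
    cohort_frame(records).to_csv(csv_path, index=False)
    meta = {
        "n_subjects": len(records),
        "groups": [r.group.name for r in records],
        "seeds": [r.seed for r in records],
        "timepoints_weeks": list(TIMEPOINTS_WEEKS),
        "stations": list(STATIONS),
        "columns": {
            "d_dia_mm": "diastolic station diameter, mm",
            "d_sys_mm": "systolic station diameter, mm",
            "h_prox_mm": "wall thickness proximal to the coarctation, mm",
            "h_dist_mm": "wall thickness distal to the coarctation, mm",
            "doppler_v_m_s": "peak Doppler jet velocity, m/s",
            "obstruction_pct": "percent area obstruction at the coarctation",
        },
    }
    json_path = out_dir / "cohort_meta.json"
    json_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    return csv_path, json_path
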