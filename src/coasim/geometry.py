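"""Longitudinal vessel geometry profiles and wall mechanics.

Builds continuous diameter profiles along the aorta from station
measurements, back-projects them to younger ages by allometric scaling with
a coarctation override, and computes the wall quantities the study tracks:
percent area obstruction, radial strain, tangent (linearized) elastic
modulus, the thin-wall modulus/strain coupling used for simulation tuning,
and normalized wall tension (pressure times systolic-beyond-diastolic
radial displacement, dyn/cm).

Coordinates: arc length s in mm, signed, 0 at the coarctation center,
proximal negative.  Lengths convert to cm internally for dyne-based
quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .cohort import StressStrainCurve, StudyGroup, coarctation_timecourse
from .units import MM_TO_CM, MMHG_TO_DYN_CM2, MMHG_TO_KPA

__all__ = [
    "GeometryProfile",
    "WallState",
    "build_diameter_profile",
    "scale_profile_to_age",
    "compute_obstruction",
    "radial_strain",
    "tangent_modulus",
    "tune_modulus",
    "forward_strain",
    "normalized_wall_tension",
    "export_surface_stl",
]


@dataclass
class GeometryProfile:
    """Continuous diameter profile d(s) with coarctation metadata.

    ``interp`` maps arc length (mm) to diastolic diameter (mm); the
    coarctation descriptor holds the throat diameter and axial length.
    """

    s_mm: np.ndarray
    d_mm: np.ndarray
    interp: PchipInterpolator
    coa_diameter_mm: float | None = None
    coa_length_mm: float = 8.0

    def __call__(self, s) -> np.ndarray | float:
        return self.interp(s)

    def reference_diameter_mm(self) -> float:
        """Profile diameter immediately proximal to the coarctation segment."""
        return float(self.interp(-0.5 * self.coa_length_mm - 1e-9))

    def obstruction_pct(self) -> float:
        if self.coa_diameter_mm is None:
            return 0.0
        return compute_obstruction(self.coa_diameter_mm, self.reference_diameter_mm())


@dataclass
class WallState:
    """Per-region wall descriptors across the four study time points."""

    region: str  # 'proximal' or 'distal'
    h_mm: np.ndarray
    e_kpa: np.ndarray
    strain_pct: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in ("proximal", "distal"):
            raise ValueError("region must be proximal or distal")
        if np.any(np.asarray(self.h_mm) <= 0) or np.any(np.asarray(self.e_kpa) <= 0):
            raise ValueError("thickness and modulus must be positive")


def build_diameter_profile(station_pairs, coa_diameter_mm: float | None = None,
                           coa_length_mm: float = 8.0) -> GeometryProfile:
    """Shape-preserving interpolant through (s, d) station measurements.

    Monotonicity-preserving piecewise cubic (no overshoot below the local
    data range); at least 3 stations with strictly increasing s.
    """
    arr = np.asarray(station_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] != 2:
        raise ValueError("need at least 3 (s, d) stations")
    s, d = arr[:, 0], arr[:, 1]
    if np.any(np.diff(s) <= 0):
        raise ValueError("station arc lengths must be strictly increasing (no duplicates)")
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    interp = PchipInterpolator(s, d)
    return GeometryProfile(s, d, interp, coa_diameter_mm=coa_diameter_mm,
                           coa_length_mm=coa_length_mm)


def scale_profile_to_age(
    profile_tp4: GeometryProfile,
    w_tp4: float,
    w_young: float,
    exponent: float = 1.0 / 3.0,
    group: StudyGroup | None = None,
    t_weeks: float | None = None,
) -> GeometryProfile:
    """Back-project a final-week profile to a younger body weight.

    Non-coarctation diameters scale by (w_young/w_tp4)**exponent; within the
    coarctation segment the diameter is overridden by the mechanistic suture
    time course (blended with a cosine window over the coarctation length)
    so that, e.g., a permanent suture holds the throat at the wire diameter
    while the surrounding aorta shrinks going younger.
    """
    if w_tp4 <= 0 or w_young <= 0:
        raise ValueError("weights must be positive")
    factor = (w_young / w_tp4) ** exponent
    s = profile_tp4.s_mm
    d = profile_tp4.d_mm * factor
    coa_d = None
    if group is not None and not group.is_control:
        if t_weeks is None:
            raise ValueError("t_weeks required for a coarctation override")
        half = 0.5 * profile_tp4.coa_length_mm
        d_ref_young = float(PchipInterpolator(s, d)(-half - 1e-9))
        coa_d = coarctation_timecourse(group, t_weeks, d_ref_young)
        window = 0.5 * (1 + np.cos(np.pi * np.clip(np.abs(s) / half, 0, 1)))
        d = d + (coa_d - d) * (np.abs(s) <= half) * window
    elif profile_tp4.coa_diameter_mm is not None:
        coa_d = profile_tp4.coa_diameter_mm * factor
        idx = int(np.argmin(np.abs(s)))
        d[idx] = coa_d
    interp = PchipInterpolator(s, d)
    return GeometryProfile(s, d, interp, coa_diameter_mm=coa_d,
                           coa_length_mm=profile_tp4.coa_length_mm)


def compute_obstruction(d_coa_mm: float, d_ref_mm: float) -> float:
    """Percent area obstruction: (1 - (d_coa/d_ref)^2) * 100."""
    if not 0 < d_coa_mm <= d_ref_mm:
        raise ValueError("need 0 < coarctation diameter <= reference diameter")
    return float((1.0 - (d_coa_mm / d_ref_mm) ** 2) * 100.0)


def invert_obstruction(obstruction_pct: float, d_ref_mm: float) -> float:
    """Coarctation diameter producing a given percent area obstruction."""
    if not 0 <= obstruction_pct < 100:
        raise ValueError("obstruction must be in [0, 100)")
    return d_ref_mm * float(np.sqrt(1.0 - obstruction_pct / 100.0))


def radial_strain(d_dia_mm: float, d_sys_mm: float) -> float:
    """Percent diameter change from diastole to systole."""
    if d_dia_mm <= 0 or d_sys_mm <= 0:
        raise ValueError("diameters must be positive")
    strain = 100.0 * (d_sys_mm - d_dia_mm) / d_dia_mm
    if strain < 0:
        warnings.warn("systolic diameter below diastolic; negative radial strain",
                      stacklevel=2)
    return strain


def tangent_modulus(curve: StressStrainCurve, strain: float) -> float:
    """Local slope d sigma/d eps (kPa) of a stress-strain curve.

    Analytic for parametric exponential curves; central difference on the
    samples otherwise.  The strain must lie within the sampled domain.
    """
    if not curve.strain[0] <= strain <= curve.strain[-1]:
        raise ValueError("strain outside the measured curve domain")
    if curve.coef_b is not None and curve.coef_a is not None:
        return float(curve.coef_a * curve.coef_b * np.exp(curve.coef_b * strain))
    if curve.coef_b == 0.0:  # linear limit
        return float((curve.stress_kpa[-1] - curve.stress_kpa[0])
                     / (curve.strain[-1] - curve.strain[0]))
    return float(PchipInterpolator(curve.strain, curve.stress_kpa).derivative()(strain))


def tune_modulus(target_strain_pct: float, h_mm: float, r_dia_mm: float, pp_mmhg: float) -> float:
    """Effective elastic modulus (kPa) producing a target radial strain.

    Thin-walled linearized tube law: E = PP * r / (eps * h) with the pulse
    pressure converted to kPa.  Exact round trip with
    :func:`forward_strain`.
    """
    if min(target_strain_pct, h_mm, r_dia_mm, pp_mmhg) <= 0:
        raise ValueError("all inputs must be positive (zero strain is singular)")
    eps = target_strain_pct / 100.0
    return float(pp_mmhg * MMHG_TO_KPA * r_dia_mm / (eps * h_mm))


def forward_strain(e_kpa: float, h_mm: float, r_dia_mm: float, pp_mmhg: float) -> float:
    """Radial strain (%) of a thin-walled tube under a pulse pressure."""
    if min(e_kpa, h_mm, r_dia_mm) <= 0 or pp_mmhg < 0:
        raise ValueError("non-physical tube-law inputs")
    return float(100.0 * pp_mmhg * MMHG_TO_KPA * r_dia_mm / (e_kpa * h_mm))


def normalized_wall_tension(p_mmhg: float, r_sys_mm: float, r_dia_mm: float) -> float:
    """Normalized wall tension (dyn/cm): pressure x radial displacement.

    The local (systolic) blood pressure in dyn/cm^2 multiplied by the
    radial displacement beyond diastole in cm.  A systolic radius below the
    diastolic one clamps the displacement to zero with a warning.
    """
    if p_mmhg < 0:
        raise ValueError("pressure must be >= 0")
    disp_mm = r_sys_mm - r_dia_mm
    if disp_mm < 0:
        warnings.warn("systolic radius below diastolic; tension clamped to 0", stacklevel=2)
        disp_mm = 0.0
    return float(p_mmhg * MMHG_TO_DYN_CM2 * disp_mm * MM_TO_CM)


def export_surface_stl(profile: GeometryProfile, path, n_theta: int = 64,
                       ds_mm: float = 1.0) -> None:
    """Write the profile as a capped surface-of-revolution ASCII STL.

    The centerline is straight along z; ring radii follow the interpolated
    diameter profile.  Units are mm.
    """
    s = np.arange(profile.s_mm[0], profile.s_mm[-1] + 0.5 * ds_mm, ds_mm)
    r = 0.5 * np.asarray(profile(s), dtype=float)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    rings = np.array([
        np.column_stack([ri * np.cos(theta), ri * np.sin(theta), np.full(n_theta, si)])
        for si, ri in zip(s, r)
    ])
    vertices = rings.reshape(-1, 3)
    faces = []
    for i in range(len(s) - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append((a, b, d))
            faces.append((a, d, c))
    # end caps (triangle fans about the ring centroids)
    c0 = len(vertices)
    vertices = np.vstack([vertices, [0, 0, s[0]], [0, 0, s[-1]]])
    for j in range(n_theta):
        faces.append((c0, (j + 1) % n_theta, j))
        base = (len(s) - 1) * n_theta
        faces.append((c0 + 1, base + j, base + (j + 1) % n_theta))
    with open(path, "w") as fh:
        fh.write("solid profile\n")
        for ia, ib, ic in faces:
            va, vb, vc = vertices[ia], vertices[ib], vertices[ic]
            n = np.cross(vb - va, vc - va)
            norm = np.linalg.norm(n)
            n = n / norm if norm > 0 else n
            fh.write(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n")
            fh.write("    outer loop\n")
            for v in (va, vb, vc):
                fh.write(f"      vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid profile\n")
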