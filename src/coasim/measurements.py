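"""Processing of flow, pressure, Doppler and geometric measurements.

These are the per-subject reduction steps between raw longitudinal
measurements and model inputs: cardiac output from the PC-MRI inflow
waveform, mean/pulse pressure from catheter traces, subclavian flow
estimation from sagittal symmetry, diameter-proportional redistribution of
the branch-flow mass defect, Doppler gradients via the simplified Bernoulli
equation, the Doppler-to-catheter gradient transfer function, severity
classification, and the obstruction-based regression used to estimate pulse
pressure at younger ages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .waveform import Waveform

__all__ = [
    "Waveform",
    "HemodynamicSummary",
    "GradientEstimate",
    "TRANSFER_SLOPE",
    "TRANSFER_INTERCEPT",
    "compute_cardiac_output",
    "summarize_pressure",
    "estimate_subclavian_flows",
    "redistribute_flow",
    "bernoulli_gradient",
    "apply_transfer",
    "fit_transfer",
    "classify_severity",
    "estimate_pp_young",
]

#: Doppler-to-catheter gradient transfer function: PIDG = slope * PIBPG + intercept.
TRANSFER_SLOPE = 1.76
TRANSFER_INTERCEPT = -6.9


@dataclass
class HemodynamicSummary:
    """Cycle-level hemodynamics for one subject/time point."""

    co_ml_s: float
    mbp_mmhg: float
    pp_mmhg: float
    hr_bpm: float

    def __post_init__(self) -> None:
        if self.co_ml_s <= 0 or self.mbp_mmhg <= 0 or self.pp_mmhg < 0:
            raise ValueError("invalid hemodynamic summary")


@dataclass
class GradientEstimate:
    """Doppler-derived gradient chain for one subject/time point.

    v_peak (m/s) -> PIDG = 4 v^2 (mmHg) -> PIBPG via the transfer function
    -> severity label from the peak-to-peak gradient.
    """

    v_peak_m_s: float
    pidg_mmhg: float
    pibpg_mmhg: float
    bpg_pp_mmhg: float
    severity_label: str


def compute_cardiac_output(q: Waveform) -> float:
    """Cycle-mean flow (ml/s): trapezoidal integral over the final cycle / period."""
    return q.cycle_mean()


def summarize_pressure(p: Waveform) -> tuple[float, float]:
    """(MBP, PP) of the final cycle: cycle mean and cycle max - min (mmHg)."""
    w = p.last_cycle()
    return w.cycle_mean(), float(w.v.max() - w.v.min())


def estimate_subclavian_flows(innominate: float, right_carotid: float) -> tuple[float, float]:
    """Estimate (right, left) subclavian mean flows (ml/s).

    The right subclavian is the innominate flow minus the right carotid
    flow; the left subclavian is assumed equal by sagittal symmetry.
    """
    if right_carotid < 0 or innominate < right_carotid:
        raise ValueError("innominate flow must be >= right carotid flow >= 0")
    right_sub = innominate - right_carotid
    return right_sub, right_sub


def redistribute_flow(inflow: float, outflows, diameters) -> list[float]:
    """Distribute the inflow/outflow mass defect proportionate to outlet diameter.

    Adds (inflow - sum(outflows)) * d_i / sum(d) to each outlet so the
    adjusted flows sum exactly to the inflow.
    """
    outflows = np.asarray(outflows, dtype=float)
    diameters = np.asarray(diameters, dtype=float)
    if outflows.size == 0 or outflows.size != diameters.size:
        raise ValueError("outflows and diameters must be same-length, non-empty")
    if np.any(diameters <= 0):
        raise ValueError("diameters must be positive")
    deficit = inflow - outflows.sum()
    adjusted = outflows + deficit * diameters / diameters.sum()
    if np.any(adjusted < 0):
        raise ValueError("redistribution produced a negative flow; measurements inconsistent")
    return adjusted.tolist()


def bernoulli_gradient(v_peak_m_s: float) -> float:
    """Simplified Bernoulli pressure gradient: 4 * v^2 (mmHg, v in m/s)."""
    if v_peak_m_s < 0:
        raise ValueError("peak velocity must be >= 0")
    return 4.0 * v_peak_m_s**2


def apply_transfer(pidg_mmhg: float) -> float:
    """Catheter-based PIBPG from Doppler PIDG via the linear transfer function.

    PIBPG = (PIDG - intercept) / slope, clamped at zero (the regression
    permits negative estimates at low Doppler gradients).
    """
    pibpg = (pidg_mmhg - TRANSFER_INTERCEPT) / TRANSFER_SLOPE
    if pibpg < 0:
        warnings.warn("transfer function produced a negative PIBPG; clamped to 0", stacklevel=2)
        return 0.0
    return pibpg


def fit_transfer(pairs) -> tuple[float, float]:
    """OLS of PIDG on PIBPG over (PIBPG, PIDG) pairs -> (slope, intercept)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least two (PIBPG, PIDG) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate PIBPG values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def classify_severity(bpg_pp_mmhg: float) -> str:
    """Clinical severity bin from the peak-to-peak gradient.

    <= 10 mmHg -> 'le10'; open interval (10, 20) -> '10to20'; >= 20 -> 'ge20'.
    """
    if bpg_pp_mmhg < 0:
        raise ValueError("gradient must be >= 0")
    if bpg_pp_mmhg <= 10:
        return "le10"
    if bpg_pp_mmhg >= 20:
        return "ge20"
    return "10to20"


def estimate_pp_young(tp4_pairs, obstruction_young: float) -> float:
    """Pulse pressure at a younger age from the obstruction regression.

    Fits OLS of final-week pulse pressure on percent area obstruction over
    (obstruction %, PP mmHg) pairs (pooled across groups by default) and
    evaluates it at the younger obstruction level.
    """
    arr = np.asarray(tp4_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need at least two (obstruction, PP) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate obstruction values")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope * obstruction_young + intercept)
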