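"""Allometric (power-law) fitting and scaling.

Power laws y = a * x**b are the standard description of how cardiovascular
quantities scale with body size.  Here they back-project geometry and
cardiac output measured at the final study week to younger ages, and map
rabbit study time to approximate human-equivalent age.

Fitting is ordinary least squares in log-log space: exact on noise-free
power-law data and reproducible, which is what the longitudinal
back-projection needs (nonlinear refits would move the anchors with every
noise draw).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "PowerLawFit",
    "fit_power_law",
    "scale_by_weight",
    "map_rabbit_to_human_age",
]

#: Human-equivalent age (years) at coarctation manifestation (study time 0).
HUMAN_AGE_AT_ONSET_YR = 7.0

# Power-law-plus-offset age map calibrated by log-log OLS to the anchors
# (weeks post-surgery -> human years): 1 -> 7.5, 3 -> 8, 10 -> 12, 20 -> 16.5.
_AGE_MAP_COEF = 0.42856
_AGE_MAP_EXP = 1.02500


@dataclass
class PowerLawFit:
    """Result of a log-log OLS fit y = a * x**b."""

    a: float
    b: float
    rss: float  # residual sum of squares in log space
    n: int

    def __post_init__(self) -> None:
        if not (self.a > 0 and np.isfinite(self.b) and self.rss >= 0):
            raise ValueError("invalid power-law fit parameters")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.a * np.asarray(x, dtype=float) ** self.b

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "PowerLawFit":
        return cls(**json.loads(s))


def fit_power_law(x, y) -> PowerLawFit:
    """Fit y = a * x**b by least squares on log y = log a + b log x.

    Requires n >= 2 strictly positive samples; recovers (a, b) exactly on
    noise-free power-law data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (x, y) samples")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fitting requires positive data")
    lx, ly = np.log(x), np.log(y)
    if np.allclose(lx, lx[0]):
        raise ValueError("degenerate x values")
    b, loga = np.polyfit(lx, ly, 1)
    resid = ly - (loga + b * lx)
    return PowerLawFit(a=float(np.exp(loga)), b=float(b), rss=float(resid @ resid), n=int(x.size))


def scale_by_weight(value_ref: float, w_ref: float, w_target: float, exponent: float) -> float:
    """Scale a reference quantity to a target body weight.

    value_target = value_ref * (w_target / w_ref)**exponent.  Cardiac output
    scales with exponent 1 (proportional to weight); diameters default to
    1/3 (geometric similarity) elsewhere in the package.
    """
    if w_ref <= 0 or w_target <= 0:
        raise ValueError("weights must be positive")
    return value_ref * (w_target / w_ref) ** exponent


def map_rabbit_to_human_age(t_weeks_post_surgery: float) -> float:
    """Approximate human-equivalent age (years) for rabbit study time (weeks).

    Monotone power-law-plus-offset map anchored at coarctation manifestation
    (~7 years) and the four study time points (~7.5, 8, 12 and 16.5 years at
    1, 3, 10 and 20 weeks post-surgery).
    """
    t = float(t_weeks_post_surgery)
    if t < 0:
        raise ValueError("time must be >= 0")
    return HUMAN_AGE_AT_ONSET_YR + _AGE_MAP_COEF * t**_AGE_MAP_EXP
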