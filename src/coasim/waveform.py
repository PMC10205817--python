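"""Uniformly sampled hemodynamic time series and synthetic waveform shapes.

A :class:`Waveform` holds either a flow trace (ml/s) or a pressure trace
(mmHg) on a uniform time grid covering one or more cardiac cycles.  The
synthesis functions build the canonical shapes used by the cohort generator:

* pressure — a two-phase cycle with a sinusoidal systolic upstroke/downstroke
  and a pure exponential diastolic decay (time constant ``tau``), scaled so
  the realized cycle mean and max-minus-min match the requested mean and
  pulse pressure;
* flow — a half-sine systolic ejection with zero diastolic flow and a
  configurable peak-to-mean ratio (default 4, a typical aortic shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Waveform",
    "generate_pressure_waveform",
    "generate_flow_waveform",
]


@dataclass
class Waveform:
    """Uniformly sampled time series over >= 1 cardiac cycle.

    Attributes
    ----------
    t : array of sample times, s (uniform grid)
    v : sample values, ml/s (flow) or mmHg (pressure)
    period : cardiac period, s
    """

    t: np.ndarray
    v: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.size == 0 or self.v.size == 0:
            raise ValueError("empty waveform")
        if self.t.shape != self.v.shape:
            raise ValueError("t and v must have the same shape")
        if self.period <= 0:
            raise ValueError("period must be positive")
        dt = np.diff(self.t)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("sampling must be uniform")
        span = self.t[-1] - self.t[0]
        # one trailing sample short is still a full cycle on a periodic grid
        if span < self.period - 1.5 * (dt[0] if dt.size else self.period):
            raise ValueError("waveform must cover at least one full period")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else self.period

    def last_cycle(self) -> "Waveform":
        """Return the final full cycle as its own waveform."""
        t_start = self.t[-1] - self.period
        mask = self.t >= t_start - 0.5 * self.dt
        return Waveform(self.t[mask], self.v[mask], self.period)

    def cycle_mean(self) -> float:
        """Time average of the final full cycle.

        Trapezoidal integration with periodic closure: on a uniform grid
        holding exactly one period this reduces to the sample mean, which
        avoids the O(dt) bias of an open-ended trapezoid.
        """
        n_per = int(round(self.period / self.dt))
        if self.v.size >= n_per > 0:
            return float(self.v[-n_per:].mean())
        w = self.last_cycle()
        return float(np.trapezoid(w.v, w.t) / (w.t[-1] - w.t[0]))


def _pressure_basis(
    n: int, period: float, tau: float, systolic_fraction: float, upstroke_fraction: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Basis waveforms a(t), b(t) so that P(t) = P_max*a + P_notch*b.

    The cycle is: cosine upstroke from end-diastolic pressure to the peak,
    cosine downstroke to the dicrotic-notch pressure, then exponential decay
    P_notch*exp(-(t-t_sys)/tau) to end diastole.  End-diastolic pressure is
    g*P_notch with g = exp(-T_dia/tau), making the trace continuous and
    periodic.  Both segments are linear in (P_max, P_notch), which lets the
    caller solve exactly for the requested mean and pulse pressure.
    """
    t = np.linspace(0.0, period, n, endpoint=False)
    t_sys = systolic_fraction * period
    t_up = upstroke_fraction * t_sys
    g = float(np.exp(-(period - t_sys) / tau))
    a = np.zeros(n)
    b = np.zeros(n)
    up = t < t_up
    s = 0.5 * (1 - np.cos(np.pi * t[up] / t_up))
    a[up] = s
    b[up] = g * (1 - s)
    down = (t >= t_up) & (t < t_sys)
    u = 0.5 * (1 - np.cos(np.pi * (t[down] - t_up) / (t_sys - t_up)))
    a[down] = 1 - u
    b[down] = u
    dia = t >= t_sys
    b[dia] = np.exp(-(t[dia] - t_sys) / tau)
    return t, a, b, g


def pressure_shape_coefficients(
    hr_bpm: float,
    tau: float,
    samples_per_cycle: int = 1000,
    systolic_fraction: float = 0.35,
    upstroke_fraction: float = 0.4,
) -> dict[str, float]:
    """Linear response of the two-phase pressure shape.

    Returns the coefficients of P_sys = alpha*MBP + beta*PP and the minimum
    feasible pulse pressure fraction (PP/MBP below which the diastolic
    decay depth alone exceeds the requested pulse and the shape degenerates).
    """
    period = 60.0 / hr_bpm
    _, a, b, g = _pressure_basis(samples_per_cycle, period, tau,
                                 systolic_fraction, upstroke_fraction)
    m_inv = np.linalg.inv(np.array([[a.mean(), b.mean()], [1.0, -g]]))
    alpha1, beta1 = m_inv[0]  # P_max row
    alpha2, beta2 = m_inv[1]  # P_notch row
    pp_min_frac = (alpha2 - alpha1) / (beta1 - beta2)
    return {"alpha": float(alpha1), "beta": float(beta1),
            "pp_min_frac": float(pp_min_frac)}


def generate_pressure_waveform(
    mbp: float,
    pp: float,
    hr_bpm: float,
    tau: float,
    n_cycles: int = 5,
    samples_per_cycle: int = 1000,
    systolic_fraction: float = 0.35,
    upstroke_fraction: float = 0.4,
) -> Waveform:
    """Synthesize a catheter-like pressure waveform.

    Parameters are the cycle mean ``mbp`` (mmHg), pulse pressure ``pp``
    (max - min, mmHg), heart rate (bpm), diastolic decay constant ``tau``
    (s) and the number of cycles.  The realized mean and pulse match the
    requests exactly on the sample grid; the diastolic segment is a pure
    exponential so its log-linear slope is -1/tau.
    """
    if pp < 0:
        raise ValueError("pulse pressure must be >= 0")
    if mbp <= pp / 2:
        raise ValueError("mean pressure must exceed half the pulse pressure")
    if tau <= 0 or hr_bpm <= 0 or n_cycles < 1:
        raise ValueError("non-physical waveform inputs")
    period = 60.0 / hr_bpm
    t1, a, b, g = _pressure_basis(
        samples_per_cycle, period, tau, systolic_fraction, upstroke_fraction
    )
    if pp == 0:
        cycle = np.full_like(t1, mbp)
    else:
        # mean: P_max*<a> + P_notch*<b> = mbp ; range: P_max - g*P_notch = pp
        abar, bbar = a.mean(), b.mean()
        m = np.array([[abar, bbar], [1.0, -g]])
        p_max, p_notch = np.linalg.solve(m, np.array([mbp, pp]))
        if not (p_max >= p_notch > 0):
            raise ValueError("requested MBP/PP/tau combination is non-physical")
        cycle = p_max * a + p_notch * b
    v = np.tile(cycle, n_cycles)
    t = np.arange(v.size) * (period / samples_per_cycle)
    return Waveform(t, v, period)


def generate_flow_waveform(
    mean_flow: float,
    hr_bpm: float,
    n_cycles: int = 5,
    peak_to_mean: float = 4.0,
    samples_per_cycle: int = 1000,
) -> Waveform:
    """Half-sine systolic ejection with zero diastolic flow.

    The systolic fraction is set by the peak-to-mean ratio: a half-sine of
    peak Q over a fraction f of the cycle has mean Q*(2/pi)*f, so
    f = (pi/2)/peak_to_mean.
    """
    if mean_flow < 0 or hr_bpm <= 0 or n_cycles < 1:
        raise ValueError("non-physical flow inputs")
    if peak_to_mean < np.pi / 2:
        raise ValueError("peak-to-mean ratio must be >= pi/2 for a half-sine")
    period = 60.0 / hr_bpm
    f_sys = (np.pi / 2) / peak_to_mean
    peak = peak_to_mean * mean_flow
    t1 = np.linspace(0.0, period, samples_per_cycle, endpoint=False)
    cycle = np.where(
        t1 < f_sys * period, peak * np.sin(np.pi * t1 / (f_sys * period)), 0.0
    )
    v = np.tile(cycle, n_cycles)
    t = np.arange(v.size) * (period / samples_per_cycle)
    return Waveform(t, v, period)
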