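"""Three-element Windkessel outlet estimation and tuning.

Each model outlet is represented by a characteristic resistance Rc in
series with a parallel compliance C / distal resistance Rd (all in mmHg,
s, ml units).  Parameters follow the standard time-constant procedure:

* tau = Rd*C is the exponential decay constant of diastolic pressure when
  flow is zero, estimated by log-linear least squares on the diastolic
  limb of a measured pressure waveform;
* C = -t / (Rd * ln(P/P0)) from an early-diastolic pressure P0 at valve
  closure to the end-diastolic pressure P (natural log);
* Rtot = MBP / mean flow, split as Rc = f*Rtot, Rd = (1-f)*Rtot with the
  Rc fraction f iteratively adjusted against the lumped network simulation.

Beyond the classical procedure, :func:`tune_compliance` rescales the outlet
time constants so the simulated inlet pulse pressure matches the measured
one — the role played by distributed wall compliance in a 3D
fluid-structure model, which a lumped network must carry in its outlets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .waveform import Waveform

__all__ = [
    "WindkesselOutlet",
    "WindkesselSet",
    "ConvergenceError",
    "estimate_tau",
    "compute_capacitance",
    "total_resistance",
    "split_rcr",
    "tune_rc_fraction",
    "tune_pulse_pressure",
]


class ConvergenceError(RuntimeError):
    """Raised when iterative outlet tuning cannot reach its targets."""


@dataclass(frozen=True)
class WindkesselOutlet:
    """One outlet's RCR parameters (mmHg*s/ml and ml/mmHg)."""

    rc: float
    rd: float
    c: float

    def __post_init__(self) -> None:
        if min(self.rc, self.rd, self.c) <= 0:
            raise ValueError("Windkessel parameters must be positive")

    @property
    def rtot(self) -> float:
        return self.rc + self.rd

    @property
    def tau(self) -> float:
        return self.rd * self.c


@dataclass
class WindkesselSet:
    """Named outlet parameters with derived totals."""

    outlets: dict[str, WindkesselOutlet]

    @property
    def rtot_parallel(self) -> float:
        return 1.0 / sum(1.0 / o.rtot for o in self.outlets.values())

    def to_json(self) -> str:
        payload = {
            name: {"Rc": o.rc, "Rd": o.rd, "C": o.c, "tau": o.tau, "Rtot": o.rtot}
            for name, o in self.outlets.items()
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def estimate_tau(p_diastole: Waveform, window_margin_frac: float = 0.1) -> float:
    """Diastolic decay constant tau (s) by log-linear least squares.

    The diastolic window starts at the steepest pressure fall (valve
    closure / dicrotic point, the maximum of -dP/dt) plus a small margin,
    and runs to end diastole.  Requires a decaying positive-pressure
    segment of at least 10 samples.
    """
    w = p_diastole.last_cycle()
    if w.v.size < 10:
        raise ValueError("need at least 10 samples")
    if np.any(w.v <= 0):
        raise ValueError("pressure must be positive")
    dpdt = np.gradient(w.v, w.t)
    start = int(np.argmin(dpdt)) + max(int(window_margin_frac * w.v.size), 1)
    t_seg = w.t[start:]
    p_seg = w.v[start:]
    if t_seg.size < 10:
        raise ValueError("diastolic window too short")
    slope, _ = np.polyfit(t_seg, np.log(p_seg), 1)
    if slope >= -1e-12:
        raise ValueError("diastolic segment is not decaying")
    return float(-1.0 / slope)


def compute_capacitance(t: float, p0: float, p: float, rd: float) -> float:
    """Windkessel compliance from a diastolic decay: C = -t / (Rd * ln(P/P0))."""
    if t <= 0 or rd <= 0:
        raise ValueError("time and distal resistance must be positive")
    if not 0 < p < p0:
        raise ValueError("pressure must decay: need 0 < P < P0")
    return float(-t / (rd * np.log(p / p0)))


def total_resistance(mbp: float, mean_flow: float) -> float:
    """Total outlet resistance Rtot = MBP / mean flow (mmHg*s/ml)."""
    if mean_flow <= 0:
        raise ValueError("mean flow must be positive")
    return mbp / mean_flow


def split_rcr(rtot: float, tau: float, rc_fraction: float) -> WindkesselOutlet:
    """Split a total resistance into an RCR outlet preserving tau = Rd*C."""
    if not 0 < rc_fraction < 1:
        raise ValueError("rc_fraction must lie in (0, 1)")
    if rtot <= 0 or tau <= 0:
        raise ValueError("rtot and tau must be positive")
    rc = rc_fraction * rtot
    rd = (1 - rc_fraction) * rtot
    return WindkesselOutlet(rc=rc, rd=rd, c=tau / rd)


def _with_fractions(network, fractions: dict[str, float], tau_by_outlet: dict[str, float]):
    outlets = {
        name: split_rcr(o.rtot, tau_by_outlet[name], fractions[name])
        for name, o in network.outlets.items()
    }
    return replace(network, outlets=outlets)


def _simulated_means(network):
    from .rom import simulate

    sol = simulate(network)
    flows = {name: sol.outlet_mean_flow(name) for name in network.outlets}
    return sol, flows, sol.inlet_mean_pressure()


def tune_rc_fraction(
    network,
    target_flows: dict[str, float],
    target_mbp: float,
    bounds: tuple[float, float] = (0.05, 0.30),
    tol: float = 0.01,
    max_iter: int = 12,
) -> dict[str, float]:
    """Adjust the Rc/Rtot fraction per outlet against the network simulation.

    Starting from the midpoint of ``bounds``, the simulated mean outlet
    flows and mean inlet pressure are compared with the targets; if outside
    ``tol`` (relative) the fraction of the worst outlet is moved by
    bisection.  Returns the per-outlet fractions; raises
    :class:`ConvergenceError` with diagnostics if the targets cannot be
    met within the bounds (mean quantities are set by the total
    resistances, so a mismatch there is not fixable by the split).
    """
    lo, hi = bounds
    if not 0 < lo < hi < 1:
        raise ValueError("bounds must satisfy 0 < lo < hi < 1")
    names = list(network.outlets)
    taus = {n: o.tau for n, o in network.outlets.items()}
    frac = {n: 0.5 * (lo + hi) for n in names}
    brackets = {n: [lo, hi] for n in names}
    last_err = None
    for _ in range(max_iter):
        net = _with_fractions(network, frac, taus)
        _, flows, mbp = _simulated_means(net)
        errs = {n: (flows[n] - target_flows[n]) / target_flows[n] for n in names}
        mbp_err = (mbp - target_mbp) / target_mbp
        last_err = {"flows": errs, "mbp": mbp_err, "fractions": dict(frac)}
        if abs(mbp_err) <= tol and all(abs(e) <= tol for e in errs.values()):
            return dict(frac)
        worst = max(names, key=lambda n: abs(errs[n]))
        b = brackets[worst]
        # outlet flow rises as its Rc share grows (transient steal); bisect
        if errs[worst] > 0:
            b[1] = frac[worst]
        else:
            b[0] = frac[worst]
        new = 0.5 * (b[0] + b[1])
        if abs(new - frac[worst]) < 1e-4:
            break
        frac[worst] = new
    raise ConvergenceError(
        f"Rc-fraction tuning failed to reach targets within bounds {bounds}: {last_err}"
    )


def tune_pulse_pressure(
    make_network,
    target_pp: float,
    rc_fractions: tuple[float, ...] = (0.02, 0.05, 0.10, 0.15, 0.22, 0.30),
    scale_bounds: tuple[float, float] = (0.01, 8.0),
    tol: float = 0.02,
    best_effort_tol: float = 0.10,
    max_bisect: int = 9,
):
    """Match the simulated inlet pulse pressure to the measured one.

    The distributed wall compliance of a 3D model has no direct analog in a
    lumped network, so two outlet degrees of freedom absorb it: the Rc
    fraction of each outlet (raises the pulse as it grows) and a common
    scale on the outlet compliances (lowers the pulse as it grows, over the
    monotone branch ``scale_bounds``).  ``make_network(rc_fraction, scale)``
    must return a ready network.  For each candidate fraction the scale
    endpoints are evaluated; the first fraction that brackets the target is
    refined by log-space bisection.  If no combination brackets it, the
    closest realized pulse within ``best_effort_tol`` (relative) is accepted
    with a warning — the wall segments themselves bound the achievable
    pulse — otherwise a :class:`ConvergenceError` is raised.

    Returns (network, (rc_fraction, scale), solution).
    """
    from .rom import simulate

    if target_pp <= 0:
        raise ValueError("target pulse pressure must be positive")
    scale_grid = tuple(
        float(s) for s in np.geomspace(scale_bounds[0], scale_bounds[1], 6)
    )

    def realized(f: float, scale: float):
        net = make_network(f, scale)
        sol = simulate(net)
        return net, sol, sol.inlet_pulse_pressure()

    best = None  # (abs err, net, (f, scale), sol)

    def consider(err, net, fs, sol):
        nonlocal best
        if best is None or err < best[0]:
            best = (err, net, fs, sol)

    for f in rc_fractions:
        # coarse sweep over the compliance scale to find a bracketing pair
        # (the pulse falls with compliance over the physical branch but can
        # flatten or turn where the stenosis pulse dominates)
        pps = []
        bracket = None
        for s in scale_grid:
            net_s, sol_s, pp_s = realized(f, s)
            consider(abs(pp_s - target_pp), net_s, (f, s), sol_s)
            if abs(pp_s - target_pp) <= tol * target_pp:
                return net_s, (f, s), sol_s
            pps.append(pp_s)
            if len(pps) > 1 and (pps[-2] - target_pp) * (pps[-1] - target_pp) < 0:
                bracket = (scale_grid[len(pps) - 2], scale_grid[len(pps) - 1],
                           pps[-2], pps[-1])
                break
        if bracket is None:
            continue
        a, b = np.log(bracket[0]), np.log(bracket[1])
        sign_a = np.sign(bracket[2] - target_pp)
        for _ in range(max_bisect):
            mid = 0.5 * (a + b)
            net_m, sol_m, pp_m = realized(f, float(np.exp(mid)))
            consider(abs(pp_m - target_pp), net_m, (f, float(np.exp(mid))), sol_m)
            if abs(pp_m - target_pp) <= tol * target_pp:
                return net_m, (f, float(np.exp(mid))), sol_m
            if np.sign(pp_m - target_pp) == sign_a:
                a = mid
            else:
                b = mid
        break
    err, net, fs, sol = best
    if err <= best_effort_tol * target_pp:
        warnings.warn(
            f"pulse-pressure tuning best effort: realized "
            f"{sol.inlet_pulse_pressure():.2f} vs target {target_pp:.2f} mmHg "
            f"(the wall segments bound the achievable pulse)",
            stacklevel=2,
        )
        return net, fs, sol
    raise ConvergenceError(
        f"pulse-pressure tuning failed: closest {sol.inlet_pulse_pressure():.2f} "
        f"vs target {target_pp:.2f} mmHg at rc_fraction={fs[0]}, scale={fs[1]:.3g}"
    )
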