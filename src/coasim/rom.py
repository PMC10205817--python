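"""Reduced-order (lumped) pulsatile hemodynamics.

A single-inlet chain of compliant segments with Windkessel (RCR) outlets
and an optional stenosis element replaces the study's 3D fluid-structure
model at desk scale.  Each segment contributes Poiseuille resistance,
blood inertance and a wall compliance from the linearized thin-wall tube
law A(P) = A_dia*(1 + (P - P_dia)*r/(E*h))^2; the stenosis element carries
a viscous (Poiseuille-in-throat) term plus a Borda-Carnot expansion-loss
term K_t*(rho/2)*(1/A_s - 1/A_0)^2 * Q|Q| whose severe-stenosis limit is
the simplified Bernoulli relation (~4 v^2 mmHg with v in m/s).

The ODE system (node pressures on compliances, segment flows through
inertances, Windkessel capacitor pressures) is integrated by backward
Euler with Newton iteration at a fixed 0.2 ms step for five cardiac
cycles from a DC (steady) initial state; the final cycle is returned and
the cycle-to-cycle mean-pressure drift is checked against 1 %.

Unit system: mmHg, s, ml throughout (cgs quantities converted on entry).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .units import CP_TO_POISE, MMHG_TO_DYN_CM2
from .waveform import Waveform
from .windkessel import WindkesselOutlet

__all__ = [
    "FluidProperties",
    "Stenosis",
    "Segment",
    "RomNetwork",
    "RomSolution",
    "SolverControls",
    "StimuliReport",
    "segment_compliance",
    "stenosis_dp",
    "simulate",
    "extract_stimuli",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood: density g/cm^3, viscosity cP."""

    density_g_cm3: float = 1.06
    viscosity_cp: float = 4.0

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0 or self.viscosity_cp <= 0:
            raise ValueError("fluid properties must be positive")

    @property
    def viscosity_poise(self) -> float:
        return self.viscosity_cp * CP_TO_POISE


@dataclass(frozen=True)
class Stenosis:
    """Discrete stenosis: throat/reference areas (cm^2), length (cm), loss Kt."""

    a_s_cm2: float
    a_0_cm2: float
    l_s_cm: float
    kt: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.a_s_cm2 <= self.a_0_cm2:
            raise ValueError("need 0 < throat area <= reference area")
        if self.l_s_cm <= 0:
            raise ValueError("stenosis length must be positive")


@dataclass(frozen=True)
class Segment:
    """Compliant vessel segment (cm / dyn-based wall properties)."""

    name: str
    length_cm: float
    r_dia_cm: float
    h_cm: float
    e_dyn_cm2: float
    stenosis: Stenosis | None = None

    def __post_init__(self) -> None:
        if min(self.length_cm, self.r_dia_cm, self.h_cm, self.e_dyn_cm2) <= 0:
            raise ValueError("segment geometry/material must be positive")

    @property
    def area_cm2(self) -> float:
        return float(np.pi * self.r_dia_cm**2)


@dataclass(frozen=True)
class SolverControls:
    dt_s: float = 2e-4
    n_cycles: int = 5
    residual_tol: float = 1e-4
    max_newton: int = 25
    drift_tol: float = 0.01
    max_extra_cycles: int = 5


@dataclass(frozen=True)
class RomNetwork:
    """Single-inlet chain: segments in series, outlets attached at nodes.

    Node i sits at the distal end of segment i (node 0 is the inlet face);
    ``outlets`` maps outlet name -> (node index, WindkesselOutlet) via
    ``outlet_nodes``.
    """

    inflow: Waveform
    segments: tuple[Segment, ...]
    outlets: dict[str, WindkesselOutlet]
    outlet_nodes: dict[str, int]
    fluid: FluidProperties = FluidProperties()
    controls: SolverControls = SolverControls()

    def __post_init__(self) -> None:
        n_nodes = len(self.segments) + 1
        if set(self.outlets) != set(self.outlet_nodes):
            raise ValueError("outlets and outlet_nodes must share keys")
        if not self.outlets:
            raise ValueError("network needs at least one outlet")
        for name, node in self.outlet_nodes.items():
            if not 0 <= node < n_nodes:
                raise ValueError(f"outlet {name!r} attached to missing node {node}")


def segment_compliance(length_cm: float, r_dia_cm: float, h_cm: float,
                       e_dyn_cm2: float) -> float:
    """Lumped segment compliance dV/dP at diastole, ml/mmHg.

    From the thin-wall tube law, C = 2*A_dia*L*r/(E*h) in cm^3 per
    dyn/cm^2, converted to ml/mmHg.
    """
    if min(length_cm, r_dia_cm, h_cm, e_dyn_cm2) <= 0:
        raise ValueError("all arguments must be positive")
    a_dia = np.pi * r_dia_cm**2
    c_cgs = 2.0 * a_dia * length_cm * r_dia_cm / (e_dyn_cm2 * h_cm)
    return float(c_cgs * MMHG_TO_DYN_CM2)


def stenosis_dp(q_ml_s: float, a_s_cm2: float, a_0_cm2: float, l_s_cm: float,
                fluid: FluidProperties = FluidProperties(), kt: float = 1.0) -> float:
    """Stenosis pressure drop (mmHg) at flow Q (ml/s).

    Viscous term 8*pi*mu*L/A_s^2 * Q plus expansion loss
    Kt*(rho/2)*(1/A_s - 1/A_0)^2 * Q|Q|; for A_s << A_0 and Kt = 1 the loss
    term approaches the simplified Bernoulli gradient 4 v^2 (v in m/s).
    """
    if not 0 < a_s_cm2 <= a_0_cm2:
        raise ValueError("need 0 < throat area <= reference area")
    mu = fluid.viscosity_poise
    lin = 8.0 * np.pi * mu * l_s_cm / a_s_cm2**2
    quad = kt * 0.5 * fluid.density_g_cm3 * (1.0 / a_s_cm2 - 1.0 / a_0_cm2) ** 2
    dp_cgs = lin * q_ml_s + quad * q_ml_s * abs(q_ml_s)
    return float(dp_cgs / MMHG_TO_DYN_CM2)


# --------------------------------------------------------------------------
# Assembly and integration
# --------------------------------------------------------------------------


class _System:
    """Assembled state-space form M x' = A x + b(t) + g(x)."""

    def __init__(self, net: RomNetwork):
        segs = net.segments
        n_seg = len(segs)
        n_node = n_seg + 1
        names = list(net.outlets)
        n_out = len(names)
        self.n_node, self.n_seg, self.names = n_node, n_seg, names
        self.iP = np.arange(n_node)
        self.iQ = n_node + np.arange(n_seg)
        self.iW = n_node + n_seg + np.arange(n_out)
        n = n_node + n_seg + n_out
        self.n = n

        mu = net.fluid.viscosity_poise
        rho = net.fluid.density_g_cm3
        c_node = np.full(n_node, 1e-8)  # floor keeps bare nodes non-singular
        self.r_seg = np.zeros(n_seg)
        self.l_seg = np.zeros(n_seg)
        self.k_sten = np.zeros(n_seg)
        for j, seg in enumerate(segs):
            c = segment_compliance(seg.length_cm, seg.r_dia_cm, seg.h_cm, seg.e_dyn_cm2)
            c_node[j] += 0.5 * c
            c_node[j + 1] += 0.5 * c
            r = 8.0 * mu * seg.length_cm / (np.pi * seg.r_dia_cm**4)
            l = rho * seg.length_cm / seg.area_cm2
            if seg.stenosis is not None:
                st = seg.stenosis
                r += 8.0 * np.pi * mu * st.l_s_cm / st.a_s_cm2**2
                self.k_sten[j] = (st.kt * 0.5 * rho
                                  * (1.0 / st.a_s_cm2 - 1.0 / st.a_0_cm2) ** 2
                                  / MMHG_TO_DYN_CM2)
            self.r_seg[j] = r / MMHG_TO_DYN_CM2
            self.l_seg[j] = l / MMHG_TO_DYN_CM2

        self.mass = np.concatenate([
            c_node, self.l_seg, [net.outlets[nm].c for nm in names]
        ])

        a = np.zeros((n, n))
        for j in range(n_seg):
            # momentum: L Q' = P_j - P_{j+1} - R Q - k Q|Q|
            a[self.iQ[j], self.iP[j]] = 1.0
            a[self.iQ[j], self.iP[j + 1]] = -1.0
            a[self.iQ[j], self.iQ[j]] = -self.r_seg[j]
            # continuity at the two end nodes
            a[self.iP[j], self.iQ[j]] += -1.0
            a[self.iP[j + 1], self.iQ[j]] += 1.0
        self.out_nodes = np.array([net.outlet_nodes[nm] for nm in names])
        self.rc = np.array([net.outlets[nm].rc for nm in names])
        self.rd = np.array([net.outlets[nm].rd for nm in names])
        for k in range(n_out):
            node, rc, rd = self.out_nodes[k], self.rc[k], self.rd[k]
            a[self.iP[node], self.iP[node]] += -1.0 / rc
            a[self.iP[node], self.iW[k]] += 1.0 / rc
            a[self.iW[k], self.iP[node]] += 1.0 / rc
            a[self.iW[k], self.iW[k]] += -1.0 / rc - 1.0 / rd
        self.a = a

    def rhs(self, x: np.ndarray, q_in: float) -> np.ndarray:
        f = self.a @ x
        f[self.iP[0]] += q_in
        q = x[self.iQ]
        f[self.iQ] -= self.k_sten * q * np.abs(q)
        return f

    def jac(self, x: np.ndarray) -> np.ndarray:
        j = self.a.copy()
        q = x[self.iQ]
        j[self.iQ, self.iQ] -= 2.0 * self.k_sten * np.abs(q)
        return j

    def dc_solve(self, q_mean: float) -> np.ndarray:
        """Steady state at the mean inflow (Newton on the algebraic system)."""
        x = np.zeros(self.n)
        for _ in range(60):
            f = self.rhs(x, q_mean)
            dx = np.linalg.solve(self.jac(x), -f)
            x = x + dx
            if np.max(np.abs(dx)) < 1e-12 * (1 + np.max(np.abs(x))):
                break
        return x


@dataclass
class RomSolution:
    """Final-cycle solution with node/segment/outlet traces."""

    t: np.ndarray
    node_pressure: np.ndarray  # (n_node, n_t), mmHg
    segment_flow: np.ndarray  # (n_seg, n_t), ml/s
    outlet_flow: dict[str, np.ndarray]  # ml/s through each outlet's Rc
    inflow: np.ndarray  # ml/s on the same grid
    period: float
    drift: float
    network: RomNetwork

    def inlet_mean_pressure(self) -> float:
        return float(self.node_pressure[0].mean())

    def inlet_pulse_pressure(self) -> float:
        return float(self.node_pressure[0].max() - self.node_pressure[0].min())

    def inlet_systolic_pressure(self) -> float:
        return float(self.node_pressure[0].max())

    def outlet_mean_flow(self, name: str) -> float:
        return float(self.outlet_flow[name].mean())

    def mean_inflow(self) -> float:
        return float(self.inflow.mean())


class SolverConvergenceError(RuntimeError):
    pass


def simulate(network: RomNetwork) -> RomSolution:
    """Integrate the network to periodicity and return the final cycle.

    Backward Euler at the configured step from a DC initial state; after
    the configured number of cycles the cycle-to-cycle mean inlet-pressure
    drift must be below the drift tolerance (extra cycles are attempted
    before raising).
    """
    sys_ = _System(network)
    ctl = network.controls
    period = network.inflow.period
    n_per = max(int(round(period / ctl.dt_s)), 8)
    dt = period / n_per  # snap so cycles tile exactly
    t_grid = np.arange(n_per) * dt
    wf = network.inflow.last_cycle()
    q_cycle = np.interp(t_grid, wf.t - wf.t[0], wf.v)

    x = sys_.dc_solve(float(q_cycle.mean()))

    def make_step(dt_step: float):
        minv_scale = sys_.mass / dt_step
        linear = not np.any(sys_.k_sten)
        if linear:
            import scipy.linalg as sla

            lu = sla.lu_factor(np.diag(minv_scale) - sys_.a)

            def step(xn: np.ndarray, q_in: float) -> np.ndarray:
                b = minv_scale * xn
                b[sys_.iP[0]] += q_in
                return sla.lu_solve(lu, b)

            return step

        def step(xn: np.ndarray, q_in: float) -> np.ndarray:
            xk = xn.copy()
            for _ in range(ctl.max_newton):
                res = minv_scale * (xk - xn) - sys_.rhs(xk, q_in)
                jac = np.diag(minv_scale) - sys_.jac(xk)
                dx = np.linalg.solve(jac, -res)
                xk = xk + dx
                if np.max(np.abs(res)) < ctl.residual_tol and np.max(np.abs(dx)) < 1e-10 * (
                    1 + np.max(np.abs(xk))
                ):
                    break
            return xk

        return step

    # Startup sweep at a coarse step: the slowest outlet time constant can
    # span several cardiac cycles, so the graded five fine cycles start from
    # a settled state rather than carrying the DC-to-periodic transient.
    tau_max = max(o.tau for o in network.outlets.values())
    n_startup = min(max(int(np.ceil(5.0 * tau_max / period)), 4), 60)
    coarse = max(n_per // 10, 4)
    step_c = make_step(period / coarse)
    q_coarse = q_cycle[:: n_per // coarse][:coarse]
    for _ in range(n_startup):
        for i in range(coarse):
            x = step_c(x, q_coarse[(i + 1) % coarse])

    step = make_step(dt)

    prev_mean = None
    drift = np.inf
    history = None
    for cycle in range(ctl.n_cycles + ctl.max_extra_cycles):
        history = np.empty((sys_.n, n_per))
        for i in range(n_per):
            x = step(x, q_cycle[(i + 1) % n_per])
            history[:, i] = x
        mean_p = history[sys_.iP[0]].mean()
        if prev_mean is not None:
            drift = abs(mean_p - prev_mean) / max(abs(prev_mean), 1e-12)
        prev_mean = mean_p
        if cycle + 1 >= ctl.n_cycles and drift < ctl.drift_tol:
            break
    else:
        raise SolverConvergenceError(
            f"periodicity not reached: mean-pressure drift {drift:.3%} "
            f"after {ctl.n_cycles + ctl.max_extra_cycles} cycles"
        )

    outlet_flow = {}
    for k, name in enumerate(sys_.names):
        node = sys_.out_nodes[k]
        outlet_flow[name] = (history[sys_.iP[node]] - history[sys_.iW[k]]) / sys_.rc[k]
    return RomSolution(
        t=t_grid,
        node_pressure=history[sys_.iP],
        segment_flow=history[sys_.iQ] if sys_.n_seg else np.empty((0, n_per)),
        outlet_flow=outlet_flow,
        inflow=np.roll(q_cycle, -1),
        period=period,
        drift=float(drift if np.isfinite(drift) else 0.0),
        network=network,
    )


# --------------------------------------------------------------------------
# Mechanical stimuli
# --------------------------------------------------------------------------


@dataclass
class StationStimuli:
    station: str
    v_peak_cm_s: float
    strain_pct: float
    tension_dyn_cm: float
    p_sys_mmhg: float


@dataclass
class StimuliReport:
    """Per-station mechanical stimuli for one simulated time point."""

    stations: list[StationStimuli]
    bpg_pp_mmhg: float

    def by_name(self, station: str) -> StationStimuli:
        for st in self.stations:
            if st.station == station:
                return st
        raise KeyError(station)

    def to_dict(self) -> dict:
        return {
            "bpg_pp_mmhg": self.bpg_pp_mmhg,
            "stations": {
                st.station: {
                    "v_peak_cm_s": st.v_peak_cm_s,
                    "strain_pct": st.strain_pct,
                    "tension_dyn_cm": st.tension_dyn_cm,
                    "p_sys_mmhg": st.p_sys_mmhg,
                }
                for st in self.stations
            },
        }


def extract_stimuli(
    solution: RomSolution,
    station_nodes: dict[str, int],
    wall: dict[str, dict],
    bpg_nodes: tuple[int, int] | None = None,
) -> StimuliReport:
    """Mechanical stimuli from a converged solution.

    ``station_nodes`` maps station name -> network node; ``wall`` maps
    station name -> {'r_dia_cm', 'h_cm', 'e_dyn_cm2'}.  Peak velocity uses
    the larger adjacent segment flow over the diastolic cross-section; the
    systolic radius follows the linearized tube law
    r(P) = r_dia*(1 + (P - P_dia)*r_dia/(E*h)); tension is the systolic
    pressure times the systolic-beyond-diastolic displacement; the
    peak-to-peak gradient is the difference of per-site pressure maxima
    (standard clinical convention).
    """
    from .geometry import normalized_wall_tension

    stations = []
    n_seg = solution.segment_flow.shape[0]
    for name, node in station_nodes.items():
        p = solution.node_pressure[node]
        w = wall[name]
        r, h, e = w["r_dia_cm"], w["h_cm"], w["e_dyn_cm2"]
        area = np.pi * r**2
        if node == 0:
            # inlet face: the prescribed inflow crosses it directly
            q_peak = float(np.max(np.abs(solution.inflow)))
        else:
            adj = [j for j in (node - 1, node) if 0 <= j < n_seg]
            q_peak = max(float(np.max(np.abs(solution.segment_flow[j]))) for j in adj) \
                if adj else float(np.max(np.abs(solution.inflow)))
        p_sys, p_dia = float(p.max()), float(p.min())
        strain = 100.0 * (p_sys - p_dia) * MMHG_TO_DYN_CM2 * r / (e * h)
        r_sys_mm = (r * 10.0) * (1.0 + strain / 100.0)
        tension = normalized_wall_tension(p_sys, r_sys_mm, r * 10.0)
        stations.append(StationStimuli(
            station=name,
            v_peak_cm_s=q_peak / area,
            strain_pct=strain,
            tension_dyn_cm=tension,
            p_sys_mmhg=p_sys,
        ))
    if bpg_nodes is None:
        bpg = 0.0
    else:
        p_prox = solution.node_pressure[bpg_nodes[0]]
        p_dist = solution.node_pressure[bpg_nodes[1]]
        bpg = float(p_prox.max() - p_dist.max())
    return StimuliReport(stations=stations, bpg_pp_mmhg=bpg)
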