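"""Constitutive equations, ODE assembly and the simulation engine.

The circuit: a constant pulmonary capillary pressure source feeds the
left atrium through a viscoelastic pulmonary venous segment; the left
atrium and ventricle are time-varying elastance chambers separated by a
diode mitral valve (linear resistance + inertance); the aortic valve is
a diode with a quadratic energy-loss term (pressure recovery via the
energy loss coefficient) plus a generic inertance; the ascending and
descending/abdominal aorta are R-L segments with viscoelastic C stores;
the supra-aortic, intercostal and terminal vascular beds are
three-element Windkessels draining to a zero venous reference.

Model flow observables:

    F1 mitral valve flow, F2 aortic valve flow, F3 ascending-aorta
    segment flow (distal ascending aorta), F4 flow entering the
    descending segment after the supra-aortic branch (aortic arch),
    F5 flow past the intercostal branch (abdominal aorta).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from . import _core
from .parameters import AvatarParameters, ChamberParams, ParameterError

__all__ = [
    "ModelState",
    "SimulationResult",
    "SimulationError",
    "elastance",
    "elastance_scale",
    "chamber_pressure",
    "mitral_gradient",
    "energy_loss_coefficient",
    "aortic_gradient",
    "assemble_rhs",
    "simulate",
    "extract_periodic_cycle",
    "pv_loop",
    "model_pressures_summary",
    "windkessel_outflows",
    "MMHG_PER_BARYE",
]

MMHG_PER_BARYE = _core.MMHG_PER_BARYE


class SimulationError(RuntimeError):
    pass


@dataclass
class ModelState:
    """Instantaneous circuit state (volumes, inertance flows, capacitor
    pressures, diode flags)."""

    V_LA: float
    V_LV: float
    Q_mv: float = 0.0
    Q_av: float = 0.0
    Q_aa: float = 0.0
    Q_da: float = 0.0
    Q_pv: float = 0.0
    P_pvc: float = 0.0
    P_caa: float = 0.0
    P_cpsa: float = 0.0
    P_cpia: float = 0.0
    P_cda: float = 0.0
    P_cpda: float = 0.0
    mv_open: bool = False
    av_open: bool = False

    def to_vector(self) -> np.ndarray:
        return np.array([
            self.V_LA, self.V_LV, self.Q_mv, self.Q_av, self.Q_aa,
            self.Q_da, self.Q_pv, self.P_pvc, self.P_caa, self.P_cpsa,
            self.P_cpia, self.P_cda, self.P_cpda,
        ])

    def validate(self) -> None:
        if self.V_LA <= 0 or self.V_LV <= 0:
            raise ValueError("chamber volumes must be positive")
        if not self.mv_open and self.Q_mv != 0.0:
            raise ValueError("Q_mv must be 0 while the mitral valve is closed")
        if not self.av_open and self.Q_av != 0.0:
            raise ValueError("Q_av must be 0 while the aortic valve is closed")


@dataclass
class SimulationResult:
    """Uniform-grid trajectories plus derived pressures and model flows."""

    t: np.ndarray
    states: np.ndarray          # (n, 13), see _core state layout
    P_LA: np.ndarray
    P_LV: np.ndarray
    P_ao: np.ndarray
    F1: np.ndarray
    F2: np.ndarray
    F3: np.ndarray
    F4: np.ndarray
    F5: np.ndarray
    dt: float
    params: AvatarParameters

    @property
    def V_LV(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def V_LA(self) -> np.ndarray:
        return self.states[:, 0]

    def flows(self) -> Tuple[np.ndarray, ...]:
        return self.F1, self.F2, self.F3, self.F4, self.F5


@functools.lru_cache(maxsize=512)
def _hill_scale(m1: float, m2: float, a1: float, a2: float) -> float:
    """1 / max of the unscaled double-Hill shape over one cycle.

    The maximum has no closed form; it is bracketed on a dense grid and
    refined with bounded scalar minimization so the scaled elastance
    peaks at E_max to better than 1e-9 relative.
    """
    tn = np.linspace(1e-9, 1.0 - 1e-9, 10_000)
    shape = _shape(tn, m1, m2, a1, a2)
    k = int(np.argmax(shape))
    lo = tn[max(k - 1, 0)]
    hi = tn[min(k + 1, len(tn) - 1)]
    res = minimize_scalar(lambda u: -_shape(u, m1, m2, a1, a2),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-13})
    peak = max(-res.fun, shape[k])
    if not np.isfinite(peak) or peak <= 0:
        raise ParameterError("double-Hill shape has no positive maximum")
    return 1.0 / peak


def _shape(tn, m1, m2, a1, a2):
    x1 = (np.asarray(tn) / a1) ** m1
    x2 = (np.asarray(tn) / a2) ** m2
    return (x1 / (1.0 + x1)) / (1.0 + x2)


def elastance_scale(ch: ChamberParams) -> float:
    """Scale factor alpha of the double-Hill elastance.

    Chosen so the maximum of alpha*E_max*shape + E_min over one cycle is
    exactly E_max (the baseline E_min rides on top of the scaled
    activation)."""
    return (_hill_scale(ch.m1, ch.m2, ch.alpha1, ch.alpha2)
            * (ch.E_max - ch.E_min) / ch.E_max)


def elastance(t, ch: ChamberParams, T: float):
    """Time-varying elastance at time ``t`` (s), cycle length ``T``.

    The activation clock is ``(t - onset) mod T`` so a negative onset
    advances activation relative to the cycle origin.
    """
    if T <= 0:
        raise ParameterError("T must be > 0")
    ch.validate()
    scale = elastance_scale(ch)
    tn = (np.asarray(t, dtype=float) - ch.onset) % T / T
    e = scale * ch.E_max * _shape(tn, ch.m1, ch.m2, ch.alpha1, ch.alpha2) + ch.E_min
    if not np.all(np.isfinite(e)):
        raise ParameterError("elastance evaluated to a non-finite value")
    return float(e) if np.isscalar(t) else e


def chamber_pressure(V: float, q: float, E: float, ch: ChamberParams) -> float:
    """P = E (V - V0) (1 - Ks q); the linear viscous loss R_visc q acts at
    the chamber outlet in the ODE assembly, not here."""
    val = E * (V - ch.V0) * (1.0 - ch.Ks * q)
    if not np.isfinite(val):
        raise ValueError("non-finite chamber pressure")
    return float(val)


def mitral_gradient(Q: float, dQdt: float, mv) -> float:
    """Transmitral pressure drop: R_mv Q + L_mv dQ/dt (open valve)."""
    return mv.R_mv * Q + mv.L_mv * dQdt


def energy_loss_coefficient(EOA_av: float, A_ao: float) -> float:
    """E_L_CO = EOA_av * A_ao / (A_ao - EOA_av), in cm^2.

    Accounts for downstream pressure recovery; undefined when the
    effective orifice reaches the aortic cross-section.
    """
    if not (0 < EOA_av < A_ao):
        raise ParameterError("energy loss coefficient requires 0 < EOA_av < A_ao")
    return EOA_av * A_ao / (A_ao - EOA_av)


def aortic_gradient(Q: float, dQdt: float, av, rho: float) -> float:
    """Transaortic pressure drop in mmHg (open valve).

    The quadratic loss term rho Q |Q| / (2 E_L_CO^2) is dimensional in
    CGS (rho g/mL, Q mL/s, areas cm^2 give barye) and is converted with
    1 mmHg = 1333.22 barye; the inertial term uses the generic valve
    inertance L_av directly in mmHg s^2/mL.
    """
    elco = energy_loss_coefficient(av.EOA_av, av.A_ao)
    quad = rho * Q * abs(Q) / (2.0 * elco * elco) * MMHG_PER_BARYE
    return quad + av.L_av * dQdt


def assemble_rhs(state: ModelState, t: float, p: AvatarParameters) -> np.ndarray:
    """Time derivative of the 13-component state for frozen diode flags."""
    pv = p.to_vector()
    dx = _core.rhs(t, state.to_vector(), pv,
                   elastance_scale(p.la), elastance_scale(p.lv),
                   state.mv_open, state.av_open)
    if not np.all(np.isfinite(dx)):
        raise SimulationError(f"non-finite state derivative at t={t}")
    return dx


def default_initial_state(p: AvatarParameters, map_estimate: float = 80.0,
                          v_lv: float = 120.0, v_la: float = 60.0) -> ModelState:
    """Start of isovolumetric contraction, both valves closed.

    The arterial stores start at a mean-pressure estimate and the
    pulmonary store at the source pressure; the 20 s horizon washes out
    this choice.
    """
    return ModelState(
        V_LA=v_la, V_LV=v_lv,
        P_pvc=p.pulm.P_pu,
        P_caa=map_estimate, P_cpsa=map_estimate, P_cpia=map_estimate,
        P_cda=map_estimate, P_cpda=map_estimate,
    )


def simulate(p: AvatarParameters, duration: float = 20.0, dt: float = 1e-3,
             initial_state: ModelState | None = None) -> SimulationResult:
    """Integrate the model with the fixed-step backward-Euler scheme.

    Starts at the onset of isovolumetric contraction with both valves
    closed and runs for ``duration`` seconds (default 20 s, long enough
    for the periodic regime).
    """
    p.validate()
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    pv = p.to_vector()
    scale_la = elastance_scale(p.la)
    scale_lv = elastance_scale(p.lv)
    if initial_state is None:
        initial_state = default_initial_state(p)
    x0 = initial_state.to_vector()
    n_steps = int(round(duration / dt))

    traj, pres, valves, status, bad_step = _core.integrate(
        pv, scale_la, scale_lv, x0, n_steps, dt)
    if status != 0:
        raise SimulationError(
            f"simulation diverged at t={bad_step * dt:.4f} s")

    t = np.arange(n_steps + 1) * dt
    q_av = traj[:, 3]
    q_aa = traj[:, 4]
    q_da = traj[:, 5]
    p2 = pres[:, 3]
    p3 = pres[:, 4]
    q_sa = (p2 - traj[:, 9]) / p.wk_sa.Rp
    q_term = (p3 - traj[:, 12]) / p.wk_da.Rp
    return SimulationResult(
        t=t, states=traj,
        P_LA=pres[:, 0], P_LV=pres[:, 1], P_ao=pres[:, 2],
        F1=traj[:, 2], F2=q_av, F3=q_aa, F4=q_aa - q_sa, F5=q_term,
        dt=dt, params=p,
    )


def windkessel_outflows(sim: SimulationResult) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flows through the three distal Windkessel resistances (to the
    venous reference)."""
    p = sim.params
    return (sim.states[:, 9] / p.wk_sa.Rd,
            sim.states[:, 10] / p.wk_ia.Rd,
            sim.states[:, 12] / p.wk_da.Rd)


def windkessel_response(wk, q_in, duration: float, dt: float = 1e-3):
    """Node-pressure response of a lone three-element Windkessel.

    ``q_in`` is the inflow in mL/s, either a scalar or an array sampled
    on the step grid.  The single capacitor state is advanced with the
    same implicit fixed-step discipline as the full model (the linear
    update is solved exactly).  Returns (t, P_node).
    """
    n = int(round(duration / dt))
    q = np.broadcast_to(np.asarray(q_in, dtype=float), (n + 1,))
    pc = np.empty(n + 1)
    pc[0] = 0.0
    a = 1.0 + dt / (wk.Rd * wk.Cp)
    for k in range(n):
        pc[k + 1] = (pc[k] + dt * q[k + 1] / wk.Cp) / a
    return np.arange(n + 1) * dt, pc + wk.Rp * q


def _slice_result(sim: SimulationResult, i0: int, i1: int) -> SimulationResult:
    sl = slice(i0, i1 + 1)
    return SimulationResult(
        t=sim.t[sl] - sim.t[i0],
        states=sim.states[sl],
        P_LA=sim.P_LA[sl], P_LV=sim.P_LV[sl], P_ao=sim.P_ao[sl],
        F1=sim.F1[sl], F2=sim.F2[sl], F3=sim.F3[sl], F4=sim.F4[sl],
        F5=sim.F5[sl], dt=sim.dt, params=sim.params,
    )


def extract_periodic_cycle(sim: SimulationResult, T: float,
                           align_to_cycle_start: bool = True) -> SimulationResult:
    """Final cycle of a simulation, time re-origined to 0.

    With ``align_to_cycle_start`` the window is the last complete cycle
    whose origin coincides with a multiple of ``T`` (the activation
    clock), so the extracted cycle is phase-aligned with measurement
    waveforms that start at the R-wave.  Otherwise the literal trailing
    window [t_end - T, t_end] is returned.
    """
    t_end = sim.t[-1]
    if t_end < 2 * T:
        raise ValueError("simulation must cover at least two cycles")
    if align_to_cycle_start:
        k = int(np.floor(t_end / T + 1e-9))
        t0, t1 = (k - 1) * T, k * T
    else:
        t0, t1 = t_end - T, t_end
    i0 = int(round(t0 / sim.dt))
    i1 = min(int(round(t1 / sim.dt)), len(sim.t) - 1)
    return _slice_result(sim, i0, i1)


def pv_loop(cycle: SimulationResult):
    """LV pressure-volume loop and stroke work.

    Stroke work is the signed loop area computed by the trapezoidal
    (shoelace-equivalent) rule, positive for the physiological
    counterclockwise traversal in the (V, P) plane.
    """
    v = np.append(cycle.V_LV, cycle.V_LV[0])
    pr = np.append(cycle.P_LV, cycle.P_LV[0])
    work = -float(np.trapezoid(pr, v))
    return cycle.V_LV, cycle.P_LV, work


def model_pressures_summary(cycle: SimulationResult) -> Tuple[float, float]:
    """Model SBP/DBP: extrema of the aortic root pressure waveform."""
    return float(np.max(cycle.P_ao)), float(np.min(cycle.P_ao))
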