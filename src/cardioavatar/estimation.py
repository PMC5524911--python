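"""Stage-two nonlinear optimization.

Minimizes the sum of squared, noise-normalized differences between the
five measured flow waveforms and their model counterparts over the 36
adjustable parameters (32 free + 4 narrow), with hard per-class bounds
honoured natively by a damped trust-region least-squares loop.  The two
closure parameters (r_dda, c_pda) are recomputed from their constraints
at every cost evaluation and are never optimized directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .initialization import (InitializationError, InitializationReport,
                             close_c_pda, close_r_dda)
from .measurements import LOCATIONS, SubjectMeasurements
from .model import SimulationError, extract_periodic_cycle, simulate
from .parameters import (NARROW_PARAMS, OPTIMIZED_PARAMS, PARAM_CLASS,
                         AvatarParameters, ParameterError)

__all__ = ["FitConfig", "FitResult", "make_bounds", "residual_vector",
           "fit", "ResidualProblem"]

DEFAULT_BOUNDS_FACTORS: Dict[str, Tuple[float, float]] = {
    "resistance": (0.5, 2.0),
    "inertance": (0.2, 5.0),
    "compliance": (1.0 / 6.0, 6.0),
    "heart": (0.5, 2.0),
    "narrow": (0.9, 1.1),
}


@dataclass
class FitConfig:
    bounds_factors: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS_FACTORS))
    termination_rel_change: float = 1e-3   # 0.1% consecutive-iterate rule
    max_iterations: int = 50
    sigma: float = 1.0
    dt: float = 1e-3
    duration: float = 20.0
    seed: int = 0
    penalty: float = 1e6
    onset_halfwidth_frac: float = 0.1      # onset bounds: p0 +/- frac * T

    def __post_init__(self) -> None:
        for cls, (lo, hi) in self.bounds_factors.items():
            if not (lo < 1.0 < hi) and cls != "narrow":
                raise ValueError(f"bounds factors for {cls} must bracket 1")
        if self.termination_rel_change <= 0:
            raise ValueError("termination_rel_change must be > 0")


@dataclass
class FitResult:
    params_hat: AvatarParameters
    J: float
    n_iter: int
    converged: bool
    cost_history: List[float]
    active_bounds: List[str]
    bounds: Dict[str, Tuple[float, float]]
    theta: Dict[str, float]

    def to_json_dict(self) -> dict:
        return {
            "schema": "cardioavatar-fit-1",
            "values": self.params_hat.to_dict(),
            "roles": self.params_hat.roles,
            "J": self.J,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "cost_history": self.cost_history,
            "active_bounds": self.active_bounds,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }


def make_bounds(p0: AvatarParameters, cfg: FitConfig,
                names: Sequence[str] = OPTIMIZED_PARAMS
                ) -> Dict[str, Tuple[float, float]]:
    """Per-parameter optimization intervals around the initial values.

    Narrow parameters get +/-10%; onsets (which may be zero or negative)
    get an additive interval of +/-``onset_halfwidth_frac * T``; all
    other parameters get the multiplicative factor of their class
    (resistance [1/2, 2], inertance [1/5, 5], compliance [1/6, 6],
    heart-chamber [1/2, 2]).
    """
    d = p0.to_dict()
    bounds: Dict[str, Tuple[float, float]] = {}
    for name in names:
        v = d[name]
        if name in NARROW_PARAMS:
            lo_f, hi_f = cfg.bounds_factors["narrow"]
            if v <= 0:
                raise ParameterError(f"{name}: narrow bounds need a positive value")
            bounds[name] = (lo_f * v, hi_f * v)
            continue
        cls = PARAM_CLASS[name]
        if cls == "onset":
            half = cfg.onset_halfwidth_frac * p0.T
            bounds[name] = (v - half, v + half)
            continue
        if v <= 0:
            raise ParameterError(f"{name}: class bounds need a positive value")
        lo_f, hi_f = cfg.bounds_factors[cls]
        bounds[name] = (lo_f * v, hi_f * v)
    return bounds


class ResidualProblem:
    """Maps an optimized-parameter vector to weighted flow residuals.

    Holds the measurement grid, the closure targets and the frozen
    (fixed) parameter values; exposes both the bounded physical space
    and the optimization bounds.
    """

    def __init__(self, meas: SubjectMeasurements, init: InitializationReport,
                 cfg: FitConfig,
                 names: Sequence[str] = OPTIMIZED_PARAMS,
                 bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                 clamp: Optional[Dict[str, float]] = None):
        self.meas = meas
        self.cfg = cfg
        self.base = dict(init.params0.to_dict())
        self.svr_target = init.svr_target
        self.c_total_target = init.c_total_target
        self.clamp = dict(clamp or {})
        self.names = [n for n in names if n not in self.clamp]
        all_bounds = bounds if bounds is not None else make_bounds(
            init.params0, cfg, names)
        self.bounds = {n: all_bounds[n] for n in self.names}
        self._t_meas = {loc: meas.waveforms[loc].t for loc in LOCATIONS}
        self._q_meas = {loc: meas.waveforms[loc].q for loc in LOCATIONS}
        self.n_residuals = sum(len(meas.waveforms[loc]) for loc in LOCATIONS)

    # -- model evaluation -----------------------------------------------------

    def build_params(self, theta: np.ndarray) -> AvatarParameters:
        d = dict(self.base)
        for name, v in self.clamp.items():
            d[name] = float(v)
        for name, v in zip(self.names, theta):
            d[name] = float(v)
        d["r_dda"] = close_r_dda(self.svr_target, d["r_aa"], d["r_da"],
                                 d["r_psa"], d["r_dsa"], d["r_pia"],
                                 d["r_dia"], d["r_pda"])
        d["c_pda"] = close_c_pda(self.c_total_target, d["c_psa"], d["c_pia"],
                                 d["c_aa"], d["c_da"])
        return AvatarParameters.from_dict(d)

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Weighted residuals (Q_meas - Q_model)/sigma over 5 waveforms.

        Simulation failures and infeasible closures yield constant
        penalty residuals so the outer loop stays alive.
        """
        try:
            p = self.build_params(theta)
            sim = simulate(p, duration=self.cfg.duration, dt=self.cfg.dt)
        except (InitializationError, SimulationError, ParameterError):
            return np.full(self.n_residuals, self.cfg.penalty)
        cycle = extract_periodic_cycle(sim, p.T, align_to_cycle_start=True)
        out = []
        for loc, q_model in zip(LOCATIONS, cycle.flows()):
            qm = np.interp(self._t_meas[loc], cycle.t, q_model)
            out.append((self._q_meas[loc] - qm) / self.cfg.sigma)
        return np.concatenate(out)

    def cost(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(r @ r)


def residual_vector(p: AvatarParameters, meas: SubjectMeasurements,
                    cfg: FitConfig) -> np.ndarray:
    """Weighted residual vector for a complete parameter set (no closure
    recomputation; the parameters are taken as given)."""
    try:
        sim = simulate(p, duration=cfg.duration, dt=cfg.dt)
    except SimulationError:
        n = sum(len(meas.waveforms[loc]) for loc in LOCATIONS)
        return np.full(n, cfg.penalty)
    cycle = extract_periodic_cycle(sim, p.T, align_to_cycle_start=True)
    out = []
    for loc, q_model in zip(LOCATIONS, cycle.flows()):
        w = meas.waveforms[loc]
        qm = np.interp(w.t, cycle.t, q_model)
        out.append((w.q - qm) / cfg.sigma)
    return np.concatenate(out)


def _lm_minimize(problem: ResidualProblem, theta0: np.ndarray, cfg: FitConfig,
                 max_iterations: Optional[int] = None,
                 xtol: Optional[float] = None,
                 improvement_tol: float = 0.25
                 ) -> Tuple[np.ndarray, float, int, bool, List[float]]:
    """Bounded damped least squares in the physical parameter space.

    Trust-region reflective iterations with Jacobian-norm scaling and an
    explicit finite-difference Jacobian (absolute steps of 1e-6 of each
    bound interval: solver-noise-robust where internal relative stepping
    is not).  The solver is restarted from its own solution while a pass
    still improves the cost by more than ``improvement_tol`` — a fresh
    trust region escapes premature small-step termination.  Returns
    (theta, cost, iterations, converged, history of accepted passes,
    monotone non-increasing).
    """
    from scipy.optimize import least_squares

    names = problem.names
    lo = np.array([problem.bounds[n][0] for n in names])
    hi = np.array([problem.bounds[n][1] for n in names])
    width = hi - lo
    n = len(names)
    max_iter = cfg.max_iterations if max_iterations is None else max_iterations
    # max_nfev counts main-loop evaluations (one per iteration); each
    # iteration additionally spends n evaluations on the Jacobian
    budget = max(max_iter, 2)
    xtol = cfg.termination_rel_change if xtol is None else xtol

    theta = np.minimum(np.maximum(theta0, lo + 1e-9 * width),
                       hi - 1e-9 * width)
    r0 = problem.residuals(theta)
    best = float(r0 @ r0)
    history = [best]
    nfev_total = 0
    converged = False
    h = 1e-6 * width

    def jac(th, *_):
        r_base = problem.residuals(th)
        out = np.empty((len(r_base), n))
        for j in range(n):
            tp = th.copy()
            if th[j] + h[j] <= hi[j]:
                tp[j] = th[j] + h[j]
            else:
                tp[j] = th[j] - h[j]
            out[:, j] = (problem.residuals(tp) - r_base) / (tp[j] - th[j])
        return out

    while budget > 0:
        try:
            out = least_squares(problem.residuals, theta, jac=jac,
                                method="trf", bounds=(lo, hi),
                                x_scale="jac", xtol=xtol, ftol=1e-12,
                                gtol=1e-14, max_nfev=budget)
        except Exception:
            break
        nfev_total += out.nfev
        budget -= out.nfev
        cost = 2.0 * float(out.cost)
        if cost < best:
            theta = out.x.copy()
            history.append(cost)
            if best - cost > improvement_tol and budget > 0:
                best = cost
                continue
            best = cost
        converged = out.status > 0
        break
    return theta, best, max(1, nfev_total), converged, history


def fit(meas: SubjectMeasurements, init: InitializationReport, cfg: FitConfig,
        start: Optional[Dict[str, float]] = None,
        max_iterations: Optional[int] = None) -> FitResult:
    """Bounded Levenberg-Marquardt fit of the 36 adjustable parameters.

    ``start`` optionally overrides individual starting values (clipped
    into bounds); closure parameters are re-derived at every evaluation.
    """
    problem = ResidualProblem(meas, init, cfg)
    d0 = init.params0.to_dict()
    theta0 = np.array([d0[n] for n in problem.names])
    if start:
        for i, n in enumerate(problem.names):
            if n in start:
                lo, hi = problem.bounds[n]
                margin = 1e-6 * (hi - lo)
                theta0[i] = min(max(start[n], lo + margin), hi - margin)
    theta, cost, n_iter, converged, history = _lm_minimize(
        problem, theta0, cfg, max_iterations=max_iterations)
    params_hat = problem.build_params(theta)
    active = []
    for i, name in enumerate(problem.names):
        lo, hi = problem.bounds[name]
        w = hi - lo
        if theta[i] - lo < 1e-3 * w or hi - theta[i] < 1e-3 * w:
            active.append(name)
    return FitResult(
        params_hat=params_hat, J=cost, n_iter=n_iter, converged=converged,
        cost_history=history, active_bounds=active, bounds=dict(problem.bounds),
        theta=dict(zip(problem.names, theta.tolist())),
    )
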