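"""Profile-likelihood identifiability analysis.

For each analyzed parameter the profile walks away from the fit optimum
in both directions with adaptive steps, re-optimizing all other
adjustable parameters at every grid point (warm-started from the
neighbouring point).  The 95% confidence boundary lies where the
profile crosses J_min + the chi-square(1 df) quantile.  Classification
follows four rules in order of precedence:

1. flat profile (total variation below tolerance) in both directions
   -> structurally non-identifiable;
2. no threshold crossing in at least one direction -> practically
   non-identifiable;
3. a crossing outside the optimization bounds -> practically
   non-identifiable;
4. otherwise -> identifiable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2

from .estimation import FitConfig, FitResult, ResidualProblem, _lm_minimize
from .initialization import InitializationReport
from .measurements import SubjectMeasurements
from .parameters import FREE_PARAMS, PARAM_CLASS

__all__ = [
    "PLConfig",
    "ProfileLikelihoodCurve",
    "pl_threshold",
    "profile_scalar_cost",
    "profile_parameter",
    "classify",
    "run_identifiability",
]

IDENTIFIABLE = "identifiable"
PRACTICAL = "practically_nonidentifiable"
STRUCTURAL = "structurally_nonidentifiable"


@dataclass
class PLConfig:
    confidence: float = 0.95
    step_target_frac: float = 0.4      # target cost rise per step (x threshold)
    max_steps: int = 50                # per direction
    range_extension: float = 3.0       # walk limit: opt bounds widened by this
    reopt_max_iter: int = 2
    reopt_skip_frac: float = 0.3       # skip re-opt while raw dJ is this small
    flat_tol_factor: float = 1e-2
    step0_frac: float = 0.05           # initial step as a fraction of scale

    def __post_init__(self) -> None:
        if not (0 < self.confidence < 1):
            raise ValueError("confidence must be in (0, 1)")


@dataclass
class ProfileLikelihoodCurve:
    param_name: str
    grid: np.ndarray
    J_profile: np.ndarray
    J_min: float
    threshold: float
    theta_opt: float
    ci_lo: float                      # value or -inf
    ci_hi: float                      # value or +inf
    ci_lo_outside: bool = False       # crossing beyond the optimization range
    ci_hi_outside: bool = False
    identifiability: str = ""
    flagged_points: List[float] = field(default_factory=list)

    def total_variation(self) -> float:
        """Profile excursion above its own floor (J_min included)."""
        if len(self.J_profile) == 0:
            return 0.0
        floor = min(float(np.min(self.J_profile)), self.J_min)
        return float(np.max(self.J_profile)) - floor


def pl_threshold(confidence: float) -> float:
    """Delta-J threshold: chi-square quantile with 1 degree of freedom
    (pointwise confidence interval)."""
    if not (0 < confidence < 1):
        raise ValueError("confidence must be in (0, 1)")
    return float(chi2.ppf(confidence, df=1))


def _walk_direction(cost_fn: Callable[[float], float], theta_opt: float,
                    J_min: float, threshold: float, direction: int,
                    walk_limit: float, step0: float, min_step: float,
                    max_step: float, cfg: PLConfig
                    ) -> Tuple[List[float], List[float], Optional[float]]:
    """Adaptive walk in one direction; returns (grid, J values, crossing).

    The step targets ``step_target_frac * threshold`` of cost increase
    per move and is doubled/halved accordingly.  The crossing is judged
    against a *running* reference (the lowest cost seen so far, which may
    drop below J_min when re-optimization at a clamped value improves on
    the base fit) and located by linear interpolation between the
    bracketing grid points.
    """
    target = cfg.step_target_frac * threshold
    step = step0
    grid: List[float] = []
    js: List[float] = []
    v_prev, j_prev = theta_opt, J_min
    v_pp: Optional[float] = None
    j_pp: Optional[float] = None
    ref = J_min
    crossing: Optional[float] = None
    for _ in range(cfg.max_steps):
        v = v_prev + direction * step
        if direction > 0 and v > walk_limit:
            v = walk_limit
        if direction < 0 and v < walk_limit:
            v = walk_limit
        j = cost_fn(v)
        grid.append(v)
        js.append(j)
        if j > ref + threshold:
            crossing = _interp_crossing(v_pp, j_pp, v_prev, j_prev, v, j,
                                        ref + threshold)
            break
        ref = min(ref, j)
        if v == walk_limit:
            break
        dj = abs(j - j_prev)
        if dj < 0.3 * target:
            step = min(step * 2.0, max_step)
        elif dj > 2.0 * target:
            step = max(step * 0.5, min_step)
        v_pp, j_pp = v_prev, j_prev
        v_prev, j_prev = v, j
    return grid, js, crossing


def _interp_crossing(v_pp, j_pp, v0, j0, v1, j1, level) -> float:
    """Locate where the profile reaches ``level`` inside [v0, v1].

    A parabola through the last three points is used when available
    (exact for locally quadratic profiles); otherwise linear
    interpolation of the bracketing pair.
    """
    lo, hi = (v0, v1) if v0 <= v1 else (v1, v0)
    if v_pp is not None and len({v_pp, v0, v1}) == 3:
        try:
            coef = np.polyfit([v_pp, v0, v1], [j_pp, j0, j1], 2)
            roots = np.roots([coef[0], coef[1], coef[2] - level])
            real = [float(r.real) for r in roots
                    if abs(r.imag) < 1e-9 and lo - 1e-12 <= r.real <= hi + 1e-12]
            if real:
                return min(real, key=lambda r: abs(r - v0))
        except np.linalg.LinAlgError:
            pass
    if j1 > j0:
        frac = (level - j0) / (j1 - j0)
    else:
        frac = 1.0
    return v0 + (v1 - v0) * min(max(frac, 0.0), 1.0)


def profile_scalar_cost(cost_fn: Callable[[float], float], theta_opt: float,
                        J_min: float, threshold: float,
                        walk_range: Tuple[float, float],
                        cfg: PLConfig, step0: Optional[float] = None,
                        param_name: str = "theta"
                        ) -> ProfileLikelihoodCurve:
    """Profile a one-dimensional (already re-optimized) cost function.

    ``cost_fn(v)`` must return the profile cost at the clamped value
    ``v``; this is the engine behind :func:`profile_parameter` and is
    directly testable against closed-form oracles.
    """
    lo_lim, hi_lim = walk_range
    scale = max(abs(theta_opt), (hi_lim - lo_lim) / 100.0, 1e-12)
    if step0 is None:
        step0 = cfg.step0_frac * scale
    min_step = 1e-3 * scale
    max_step = 10.0 * scale

    g_up, j_up, cross_up = _walk_direction(
        cost_fn, theta_opt, J_min, threshold, +1, hi_lim, step0,
        min_step, max_step, cfg)
    g_dn, j_dn, cross_dn = _walk_direction(
        cost_fn, theta_opt, J_min, threshold, -1, lo_lim, step0,
        min_step, max_step, cfg)

    grid = np.array(list(reversed(g_dn)) + [theta_opt] + g_up)
    js = np.array(list(reversed(j_dn)) + [J_min] + j_up)
    return ProfileLikelihoodCurve(
        param_name=param_name, grid=grid, J_profile=js, J_min=J_min,
        threshold=threshold, theta_opt=theta_opt,
        ci_lo=cross_dn if cross_dn is not None else -math.inf,
        ci_hi=cross_up if cross_up is not None else math.inf,
    )


def classify(curve: ProfileLikelihoodCurve,
             opt_bounds: Tuple[float, float], flat_tol_factor: float = 1e-2
             ) -> str:
    """Three-way identifiability class from the completed curve.

    The flatness tolerance scales with the cost floor but is capped at
    half the threshold: a profile whose variation reaches the
    chi-square threshold is never "flat", however large J_min is.
    """
    flat_tol = min(flat_tol_factor * max(1.0, curve.J_min),
                   0.5 * curve.threshold)
    if curve.total_variation() < flat_tol:
        return STRUCTURAL
    if math.isinf(curve.ci_lo) or math.isinf(curve.ci_hi):
        return PRACTICAL
    lo, hi = opt_bounds
    if curve.ci_lo < lo or curve.ci_hi > hi:
        return PRACTICAL
    return IDENTIFIABLE


def _walk_range(name: str, opt_bounds: Tuple[float, float],
                extension: float) -> Tuple[float, float]:
    lo, hi = opt_bounds
    if PARAM_CLASS[name] == "onset":
        half = (hi - lo) / 2.0
        mid = (hi + lo) / 2.0
        return (mid - extension * half, mid + extension * half)
    return (lo / extension, hi * extension)


def profile_parameter(name: str, fit_result: FitResult,
                      meas: SubjectMeasurements, init: InitializationReport,
                      fit_cfg: FitConfig, pl_cfg: PLConfig
                      ) -> ProfileLikelihoodCurve:
    """Profile likelihood of one model parameter around a completed fit.

    All other adjustable parameters are re-optimized at each grid point
    (warm-started from the previous point).  Re-optimization is skipped
    while the raw cost stays within ``reopt_skip_frac`` of the
    threshold: it could only lower the profile further below the
    threshold, so the classification outcome is unchanged.
    """
    if name not in fit_result.theta:
        raise KeyError(f"{name} was not optimized in the supplied fit")
    threshold = pl_threshold(pl_cfg.confidence)
    theta_opt = fit_result.theta[name]
    J_min = fit_result.J
    opt_bounds = fit_result.bounds[name]

    warm: Dict[str, float] = dict(fit_result.theta)
    warm.pop(name)
    flagged: List[float] = []
    best_seen = [J_min]

    def cost_fn(v: float) -> float:
        problem = ResidualProblem(meas, init, fit_cfg, clamp={name: v})
        theta_warm = np.array([warm[n] for n in problem.names])
        for i, n in enumerate(problem.names):
            lo, hi = problem.bounds[n]
            m = 1e-9 * (hi - lo)
            theta_warm[i] = min(max(theta_warm[i], lo + m), hi - m)
        raw = problem.cost(theta_warm)
        if raw - best_seen[0] < pl_cfg.reopt_skip_frac * threshold:
            return raw
        theta_new, cost, _, _, _ = _lm_minimize(
            problem, theta_warm, fit_cfg,
            max_iterations=pl_cfg.reopt_max_iter, xtol=1e-10)
        if cost > raw + 1e-9:
            flagged.append(v)
            cost = raw
        else:
            for n, val in zip(problem.names, theta_new):
                warm[n] = float(val)
        best_seen[0] = min(best_seen[0], cost)
        return min(cost, raw)

    curve = profile_scalar_cost(
        cost_fn, theta_opt, J_min, threshold,
        _walk_range(name, opt_bounds, pl_cfg.range_extension),
        pl_cfg, param_name=name)
    curve.flagged_points = flagged
    curve.ci_lo_outside = (not math.isinf(curve.ci_lo)
                           and curve.ci_lo < opt_bounds[0])
    curve.ci_hi_outside = (not math.isinf(curve.ci_hi)
                           and curve.ci_hi > opt_bounds[1])
    curve.identifiability = classify(curve, opt_bounds, pl_cfg.flat_tol_factor)
    return curve


def run_identifiability(fit_result: FitResult, meas: SubjectMeasurements,
                        init: InitializationReport, fit_cfg: FitConfig,
                        pl_cfg: PLConfig,
                        params: Optional[Sequence[str]] = None,
                        progress: Optional[Callable[[str], None]] = None
                        ) -> Dict[str, ProfileLikelihoodCurve]:
    """Profile every analyzed parameter (default: the 32 free ones)."""
    if params is None:
        params = [n for n in FREE_PARAMS if n in fit_result.theta]
    curves = {}
    for name in params:
        if progress is not None:
            progress(name)
        curves[name] = profile_parameter(name, fit_result, meas, init,
                                         fit_cfg, pl_cfg)
    return curves


def report_table(curves: Dict[str, ProfileLikelihoodCurve]) -> List[dict]:
    """Flat report rows: estimate, CI bounds, class."""
    rows = []
    for name, c in curves.items():
        rows.append({
            "parameter": name,
            "estimate": c.theta_opt,
            "ci_lo": None if math.isinf(c.ci_lo) else c.ci_lo,
            "ci_hi": None if math.isinf(c.ci_hi) else c.ci_hi,
            "ci_lo_infinite": math.isinf(c.ci_lo),
            "ci_hi_infinite": math.isinf(c.ci_hi),
            "ci_outside_bounds": c.ci_lo_outside or c.ci_hi_outside,
            "identifiability": c.identifiability,
        })
    return rows


def save_report(curves: Dict[str, ProfileLikelihoodCurve], path) -> None:
    payload = {
        "schema": "cardioavatar-pl-1",
        "rows": report_table(curves),
        "curves": {
            name: {"grid": c.grid.tolist(), "J_profile": c.J_profile.tolist(),
                   "J_min": c.J_min, "threshold": c.threshold}
            for name, c in curves.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
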