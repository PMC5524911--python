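"""Numba-compiled numerics: circuit right-hand side and the fixed-step
implicit (backward Euler + Newton) integrator.

State vector layout (13 continuous states):

    0  V_LA     left atrial volume              [mL]
    1  V_LV     left ventricular volume         [mL]
    2  Q_mv     mitral valve flow               [mL/s]
    3  Q_av     aortic valve flow               [mL/s]
    4  Q_aa     ascending-aorta inertance flow  [mL/s]
    5  Q_da     descending-aorta inertance flow [mL/s]
    6  Q_pv     pulmonary venous inertance flow [mL/s]
    7  P_pvc    pulmonary viscoelastic store    [mmHg]
    8  P_caa    ascending-aorta store           [mmHg]
    9  P_cpsa   supra-aortic windkessel cap     [mmHg]
    10 P_cpia   intercostal windkessel cap      [mmHg]
    11 P_cda    descending-aorta store          [mmHg]
    12 P_cpda   terminal windkessel cap         [mmHg]

Parameters arrive as the canonical 50-vector (see
``parameters.PARAM_NAMES``) plus the two precomputed double-Hill scale
factors.  All pressures in mmHg, flows in mL/s, times in s; the
quadratic valve-loss term is evaluated in CGS and converted with
1 mmHg = 1333.22 barye.
"""

import numpy as np
from numba import njit

NSTATE = 13

# Parameter indices (must mirror parameters.PARAM_NAMES).
(E_MIN_LA, E_MAX_LA, V0_LA, M1_LA, M2_LA, A1_LA, A2_LA, KS_LA, RV_LA, ON_LA,
 E_MIN_LV, E_MAX_LV, V0_LV, M1_LV, M2_LV, A1_LV, A2_LV, KS_LV, RV_LV, ON_LV,
 R_MV, L_MV,
 EOA_AV, A_AO, L_AV,
 R_AA, L_AA, R_AAV, C_AA,
 R_DA, L_DA, R_DAV, C_DA,
 R_PSA, R_DSA, C_PSA,
 R_PIA, R_DIA, C_PIA,
 R_PDA, R_DDA, C_PDA,
 P_PU, R_PU, R_PV, L_PV, R_PVC, C_PVC,
 T_CYCLE, RHO) = range(50)

MMHG_PER_BARYE = 1.0 / 1333.22


@njit(cache=True)
def double_hill(t_rel_norm, m1, m2, a1, a2):
    """Unscaled double-Hill shape at normalized cycle time in [0, 1)."""
    x1 = (t_rel_norm / a1) ** m1
    x2 = (t_rel_norm / a2) ** m2
    return (x1 / (1.0 + x1)) * (1.0 / (1.0 + x2))


@njit(cache=True)
def elastance_scalar(t, e_min, e_max, m1, m2, a1, a2, onset, T, scale):
    tn = ((t - onset) % T) / T
    return scale * e_max * double_hill(tn, m1, m2, a1, a2) + e_min


@njit(cache=True)
def rhs(t, x, pv, scale_la, scale_lv, mv_open, av_open):
    """Circuit conservation laws; returns dx/dt for frozen valve states."""
    dx = np.zeros(NSTATE)
    T = pv[T_CYCLE]

    v_la, v_lv = x[0], x[1]
    q_mv, q_av, q_aa, q_da, q_pv = x[2], x[3], x[4], x[5], x[6]
    p_pvc, p_caa, p_cpsa, p_cpia, p_cda, p_cpda = (
        x[7], x[8], x[9], x[10], x[11], x[12])

    e_la = elastance_scalar(t, pv[E_MIN_LA], pv[E_MAX_LA], pv[M1_LA], pv[M2_LA],
                            pv[A1_LA], pv[A2_LA], pv[ON_LA], T, scale_la)
    e_lv = elastance_scalar(t, pv[E_MIN_LV], pv[E_MAX_LV], pv[M1_LV], pv[M2_LV],
                            pv[A1_LV], pv[A2_LV], pv[ON_LV], T, scale_lv)

    p_la = e_la * (v_la - pv[V0_LA]) * (1.0 - pv[KS_LA] * q_mv)
    p_lv = e_lv * (v_lv - pv[V0_LV]) * (1.0 - pv[KS_LV] * q_av)

    # Pulmonary inlet node: source through R_pu, viscoelastic store, L_pv out.
    p_pul = ((pv[P_PU] / pv[R_PU] + p_pvc / pv[R_PVC] - q_pv)
             / (1.0 / pv[R_PU] + 1.0 / pv[R_PVC]))

    # Aortic root node: valve inflow splits into C_aa store and segment flow.
    p_ao = p_caa + pv[R_AAV] * (q_av - q_aa)

    # Node after the ascending segment: supra-aortic windkessel + C_da store
    # + descending segment.
    p2 = ((q_aa - q_da + p_cpsa / pv[R_PSA] + p_cda / pv[R_DAV])
          / (1.0 / pv[R_PSA] + 1.0 / pv[R_DAV]))

    # Node after the descending segment: intercostal + terminal windkessels.
    p3 = ((q_da + p_cpia / pv[R_PIA] + p_cpda / pv[R_PDA])
          / (1.0 / pv[R_PIA] + 1.0 / pv[R_PDA]))

    q_sa = (p2 - p_cpsa) / pv[R_PSA]
    q_cda = (p2 - p_cda) / pv[R_DAV]
    q_ia = (p3 - p_cpia) / pv[R_PIA]
    q_term = (p3 - p_cpda) / pv[R_PDA]

    dx[0] = q_pv - q_mv
    dx[1] = q_mv - q_av

    if mv_open:
        dx[2] = (p_la - pv[RV_LA] * q_mv - p_lv - pv[R_MV] * q_mv) / pv[L_MV]
    if av_open:
        elco = pv[EOA_AV] * pv[A_AO] / (pv[A_AO] - pv[EOA_AV])
        dp_quad = (pv[RHO] * q_av * abs(q_av) / (2.0 * elco * elco)
                   * MMHG_PER_BARYE)
        dx[3] = (p_lv - pv[RV_LV] * q_av - p_ao - dp_quad) / pv[L_AV]

    dx[4] = (p_ao - pv[R_AA] * q_aa - p2) / pv[L_AA]
    dx[5] = (p2 - pv[R_DA] * q_da - p3) / pv[L_DA]
    dx[6] = (p_pul - pv[R_PV] * q_pv - p_la) / pv[L_PV]

    dx[7] = (p_pul - p_pvc) / pv[R_PVC] / pv[C_PVC]
    dx[8] = (q_av - q_aa) / pv[C_AA]
    dx[9] = (q_sa - p_cpsa / pv[R_DSA]) / pv[C_PSA]
    dx[10] = (q_ia - p_cpia / pv[R_DIA]) / pv[C_PIA]
    dx[11] = q_cda / pv[C_DA]
    dx[12] = (q_term - p_cpda / pv[R_DDA]) / pv[C_PDA]
    return dx


@njit(cache=True)
def node_pressures(t, x, pv, scale_la, scale_lv):
    """Derived pressures (P_LA, P_LV, P_ao, P2, P3) at a state."""
    T = pv[T_CYCLE]
    e_la = elastance_scalar(t, pv[E_MIN_LA], pv[E_MAX_LA], pv[M1_LA], pv[M2_LA],
                            pv[A1_LA], pv[A2_LA], pv[ON_LA], T, scale_la)
    e_lv = elastance_scalar(t, pv[E_MIN_LV], pv[E_MAX_LV], pv[M1_LV], pv[M2_LV],
                            pv[A1_LV], pv[A2_LV], pv[ON_LV], T, scale_lv)
    p_la = e_la * (x[0] - pv[V0_LA]) * (1.0 - pv[KS_LA] * x[2])
    p_lv = e_lv * (x[1] - pv[V0_LV]) * (1.0 - pv[KS_LV] * x[3])
    p_ao = x[8] + pv[R_AAV] * (x[3] - x[4])
    p2 = ((x[4] - x[5] + x[9] / pv[R_PSA] + x[11] / pv[R_DAV])
          / (1.0 / pv[R_PSA] + 1.0 / pv[R_DAV]))
    p3 = ((x[5] + x[10] / pv[R_PIA] + x[12] / pv[R_PDA])
          / (1.0 / pv[R_PIA] + 1.0 / pv[R_PDA]))
    return p_la, p_lv, p_ao, p2, p3


@njit(cache=True)
def _newton_matrix(t_new, x, pv, scale_la, scale_lv, mv_open, av_open,
                   dt, theta):
    """Inverse Newton matrix inv(I - theta*dt*J) from a forward-difference
    Jacobian of the RHS; returns (matrix, ok flag)."""
    f = rhs(t_new, x, pv, scale_la, scale_lv, mv_open, av_open)
    jac = np.empty((NSTATE, NSTATE))
    for j in range(NSTATE):
        h = 1e-6 * max(abs(x[j]), 1.0)
        xp = x.copy()
        xp[j] += h
        fp = rhs(t_new, xp, pv, scale_la, scale_lv, mv_open, av_open)
        for i in range(NSTATE):
            jac[i, j] = (fp[i] - f[i]) / h
    for i in range(NSTATE):
        for j in range(NSTATE):
            if not np.isfinite(jac[i, j]):
                return np.eye(NSTATE), False
    return np.ascontiguousarray(np.linalg.inv(np.eye(NSTATE) - theta * dt * jac)), True


@njit(cache=True)
def _newton_iterate(t_old, t_new, x_old, pv, scale_la, scale_lv,
                    mv_open, av_open, dt, theta, a_inv):
    """Solve one theta-method step with <=4 chord-Newton iterations using
    the supplied (possibly stale) Newton matrix; returns (x, residual)."""
    f_old = rhs(t_old, x_old, pv, scale_la, scale_lv, mv_open, av_open)
    x = x_old + dt * f_old  # explicit predictor
    f = rhs(t_new, x, pv, scale_la, scale_lv, mv_open, av_open)
    nrm = np.inf
    for _ in range(4):
        res = x - x_old - dt * ((1.0 - theta) * f_old + theta * f)
        x = x - a_inv @ res
        f = rhs(t_new, x, pv, scale_la, scale_lv, mv_open, av_open)
        nrm = 0.0
        for i in range(NSTATE):
            if abs(res[i]) > nrm:
                nrm = abs(res[i])
        if nrm < 1e-10:
            break
    return x, nrm


@njit(cache=True)
def _implicit_step(t_old, t_new, x_old, pv, scale_la, scale_lv,
                   mv_open, av_open, dt, theta):
    """One theta-method step with a freshly built Newton matrix.

    theta = 1 gives backward Euler, theta = 0.5 the (A-stable,
    second-order) trapezoidal rule.
    """
    a_inv, ok = _newton_matrix(t_new, x_old, pv, scale_la, scale_lv,
                               mv_open, av_open, dt, theta)
    if not ok:
        return x_old + np.full(NSTATE, np.nan)
    x, _ = _newton_iterate(t_old, t_new, x_old, pv, scale_la, scale_lv,
                           mv_open, av_open, dt, theta, a_inv)
    return x


@njit(cache=True)
def integrate(pv, scale_la, scale_lv, x0, n_steps, dt, theta=0.5):
    """Fixed-step implicit integration with diode valve switching.

    A valve opens when the upstream-minus-downstream pressure gradient
    turns positive while closed; it closes (flow clamped to zero) when
    its flow crosses zero from above.  Returns the trajectory, derived
    pressures, valve-state flags and a status code (0 = ok, 1 = non-finite
    or out-of-range state, reported with the offending step index).
    """
    traj = np.empty((n_steps + 1, NSTATE))
    pres = np.empty((n_steps + 1, 5))
    valves = np.zeros((n_steps + 1, 2), dtype=np.int8)
    x = x0.copy()
    mv_open = False
    av_open = False
    traj[0] = x
    p_la, p_lv, p_ao, p2, p3 = node_pressures(0.0, x, pv, scale_la, scale_lv)
    pres[0, 0], pres[0, 1], pres[0, 2], pres[0, 3], pres[0, 4] = (
        p_la, p_lv, p_ao, p2, p3)

    status = 0
    bad_step = -1
    # the Newton matrix is reused across steps and rebuilt on valve
    # transitions or when the chord iteration converges poorly
    a_inv, ok = _newton_matrix(0.0, x, pv, scale_la, scale_lv,
                               mv_open, av_open, dt, theta)
    if not ok:
        status = 1
        bad_step = 0
        return traj, pres, valves, status, bad_step
    for k in range(1, n_steps + 1):
        t_new = k * dt
        x_prev = x
        x, nrm = _newton_iterate(t_new - dt, t_new, x_prev, pv, scale_la,
                                 scale_lv, mv_open, av_open, dt, theta, a_inv)
        if not (nrm < 3e-8):
            # stale matrix: rebuild at the current state and redo the step
            a_inv, ok = _newton_matrix(t_new, x_prev, pv, scale_la, scale_lv,
                                       mv_open, av_open, dt, theta)
            if not ok:
                status = 1
                bad_step = k
                for kk in range(k, n_steps + 1):
                    traj[kk] = x
                    pres[kk, :] = 0.0
                break
            x, nrm = _newton_iterate(t_new - dt, t_new, x_prev, pv, scale_la,
                                     scale_lv, mv_open, av_open, dt, theta,
                                     a_inv)

        mv_was, av_was = mv_open, av_open

        # closing: flow crossed zero from above
        if mv_open and x[2] <= 0.0:
            mv_open = False
            x[2] = 0.0
        if av_open and x[3] <= 0.0:
            av_open = False
            x[3] = 0.0

        p_la, p_lv, p_ao, p2, p3 = node_pressures(
            t_new, x, pv, scale_la, scale_lv)

        # opening: forward pressure gradient across the closed diode
        if not mv_open and (p_la - p_lv) > 0.0:
            mv_open = True
        if not av_open and (p_lv - p_ao) > 0.0:
            av_open = True

        if mv_open != mv_was or av_open != av_was:
            a_inv, ok_j = _newton_matrix(t_new, x, pv, scale_la, scale_lv,
                                         mv_open, av_open, dt, theta)
            if not ok_j:
                status = 1
                bad_step = k
                for kk in range(k, n_steps + 1):
                    traj[kk] = x
                    pres[kk, :] = 0.0
                break

        ok = True
        for i in range(NSTATE):
            if not np.isfinite(x[i]) or abs(x[i]) > 1e7:
                ok = False
        if x[0] <= 0.0 or x[1] <= 0.0:
            ok = False
        if not ok:
            status = 1
            bad_step = k
            for kk in range(k, n_steps + 1):
                traj[kk] = x
                pres[kk, :] = 0.0
            break

        traj[k] = x
        pres[k, 0], pres[k, 1], pres[k, 2], pres[k, 3], pres[k, 4] = (
            p_la, p_lv, p_ao, p2, p3)
        valves[k, 0] = 1 if mv_open else 0
        valves[k, 1] = 1 if av_open else 0

    return traj, pres, valves, status, bad_step
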