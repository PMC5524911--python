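"""Stage-one parameter estimation: measured/derived initial values,
role assignment and the two closure relations.

Twelve parameters are set from the measurements: {EOA_av, A_ao, R_psa,
R_pia, R_pda, C_pda, R_dda, T, E_max_LV, V0_LV, R_dia, R_dsa}.  Of
those, R_dda and C_pda stay closure-defined during optimization (they
re-close the network DC resistance to SVR and the total compliance to
SV/PP at every cost evaluation); E_max_LV, V0_LV, R_dia and R_dsa are
optimized within +/-10%.  Everything else starts from healthy-adult
literature values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .measurements import (ClinicalIndices, SubjectMeasurements,
                           branch_mean_flows, compute_indices, eoa_continuity,
                           net_volume)
from .parameters import (LITERATURE_VALUES, AvatarParameters, ParameterError,
                         default_roles)

__all__ = [
    "InitializationReport",
    "emax_lv_initial",
    "single_beat_ees",
    "v0_lv_single_beat",
    "systemic_resistances",
    "peripheral_compliances",
    "close_r_dda",
    "close_c_pda",
    "network_dc_resistance",
    "build_initial_parameters",
]


class InitializationError(ValueError):
    pass


@dataclass
class InitializationReport:
    params0: AvatarParameters
    provenance: Dict[str, str]
    indices: ClinicalIndices
    svr_target: float       # mmHg s/mL, closure target for r_dda
    c_total_target: float   # mL/mmHg, closure target for c_pda
    v0_clamped: bool = False

    def to_json(self, path) -> None:
        payload = {
            "schema": "cardioavatar-init-1",
            "values": self.params0.to_dict(),
            "roles": self.params0.roles,
            "provenance": self.provenance,
            "svr_target": self.svr_target,
            "c_total_target": self.c_total_target,
            "v0_clamped": self.v0_clamped,
            "indices": vars(self.indices),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def emax_lv_initial(Pes_LV: float, ESV: float, V0_LV: float) -> float:
    """Maximal LV elastance from end-systolic pressure and volume:
    Pes / (ESV - V0)."""
    if ESV <= V0_LV:
        raise InitializationError("ESV must exceed V0_LV")
    return Pes_LV / (ESV - V0_LV)


# Polynomial for the group-averaged normalized elastance at ejection
# onset as a function of the pre-ejection/total-systole timing ratio
# (single-beat method of Chen et al., JACC 2001).
_END_COEFFS = (0.35695, -7.2266, 74.249, -307.39, 684.54,
               -856.92, 571.95, -159.1)


def single_beat_ees(SBP: float, DBP: float, SV: float, EF: float,
                    tnd: float, dPav_max: float = 0.0) -> float:
    """Non-invasive single-beat estimate of LV end-systolic elastance.

    Uses cuff pressures, stroke volume, ejection fraction and the
    pre-ejection to total-systole timing ratio ``tnd`` (Chen et al.,
    2001): Ees = [DBP - ENd * Pes] / (ENd * SV) with Pes = 0.9 * (SBP +
    peak transaortic gradient).
    """
    if not (0 < tnd < 1):
        raise InitializationError("timing ratio must be in (0, 1)")
    if SV <= 0 or not (0 < EF < 1):
        raise InitializationError("need SV > 0 and 0 < EF < 1")
    end_avg = sum(c * tnd ** i for i, c in enumerate(_END_COEFFS))
    pes = 0.9 * (SBP + dPav_max)
    end_est = 0.0275 - 0.165 * EF + 0.3656 * (DBP / pes) + 0.515 * end_avg
    if end_est <= 0:
        raise InitializationError("single-beat normalized elastance <= 0")
    ees = (DBP - end_est * pes) / (end_est * SV)
    if ees <= 0:
        raise InitializationError("single-beat Ees estimate <= 0")
    return ees


def _systolic_timing_ratio(meas: SubjectMeasurements,
                           threshold: float = 0.05) -> float:
    """Pre-ejection / total-systole ratio from the F2 upstroke.

    Ejection onset (end) is the first (last) time the aortic-valve flow
    rises above (falls below) ``threshold`` times its peak; the cycle
    origin is the R-wave.
    """
    w = meas.waveforms["F2"]
    peak = float(np.max(w.q))
    if peak <= 0:
        raise InitializationError("aortic-valve waveform has no systolic pulse")
    above = w.q >= threshold * peak
    if not above.any():
        raise InitializationError("aortic-valve waveform has no systolic pulse")
    idx = np.flatnonzero(above)
    t_on = w.t[idx[0]]
    t_off = w.t[idx[-1]]
    if t_off <= t_on or t_on <= 0:
        # upstroke at the very first frame: assume one frame of pre-ejection
        t_on = max(t_on, w.t[1] * 0.5)
    return float(t_on / t_off) if t_off > 0 else 0.3


def v0_lv_single_beat(meas: SubjectMeasurements, indices: ClinicalIndices
                      ) -> Tuple[float, bool]:
    """Unstressed LV volume via the single-beat elastance estimate:
    V0 = ESV - Pes / Ees, clamped to [0, ESV/2].

    Returns ``(V0, clamped)``.
    """
    tnd = _systolic_timing_ratio(meas)
    ees = single_beat_ees(meas.SBP, meas.DBP, indices.SV, indices.EF,
                          tnd, indices.dPav_max)
    v0 = meas.ESV - indices.Pes_LV / ees
    lo, hi = 0.0, meas.ESV / 2.0
    clamped = not (lo <= v0 <= hi)
    return float(min(max(v0, lo), hi)), clamped


def characteristic_impedance(L: float, C: float) -> float:
    """sqrt(L/C) of the feeding vessel segment."""
    return float(np.sqrt(L / C))


def systemic_resistances(indices: ClinicalIndices,
                         branch_means: Tuple[float, float, float],
                         r_aa: float, r_da: float,
                         l_aa: float, c_aa: float,
                         l_da: float, c_da: float) -> Dict[str, float]:
    """Initial Windkessel resistances.

    Proximal resistances match the characteristic impedance of the
    feeding segment; distal resistances set each branch's total DC
    resistance to MAP over the branch mean flow (aortic mean pressure
    losses disregarded at initialization); R_dda closes the full network
    DC resistance to SVR = MAP/CO.
    """
    q_sa, q_ia, q_term = branch_means
    if min(q_sa, q_ia, q_term) <= 0 or indices.MAP <= 0:
        raise InitializationError("need positive branch flows and MAP")
    r_psa = characteristic_impedance(l_aa, c_aa)
    r_pia = characteristic_impedance(l_da, c_da)
    r_pda = characteristic_impedance(l_da, c_da)
    r_dsa = indices.MAP / q_sa - r_psa
    r_dia = indices.MAP / q_ia - r_pia
    if r_dsa <= 0 or r_dia <= 0:
        raise InitializationError("non-positive distal resistance at init")
    r_dda = close_r_dda(indices.SVR, r_aa, r_da, r_psa, r_dsa,
                        r_pia, r_dia, r_pda)
    return {"r_psa": r_psa, "r_pia": r_pia, "r_pda": r_pda,
            "r_dsa": r_dsa, "r_dia": r_dia, "r_dda": r_dda}


def _parallel(a: float, b: float) -> float:
    return a * b / (a + b)


def network_dc_resistance(r_aa: float, r_da: float, r_psa: float,
                          r_dsa: float, r_pia: float, r_dia: float,
                          r_pda: float, r_dda: float) -> float:
    """DC (mean-flow) resistance of the arterial network seen from the
    aortic root."""
    branch2 = r_da + _parallel(r_pia + r_dia, r_pda + r_dda)
    return r_aa + _parallel(r_psa + r_dsa, branch2)


def close_r_dda(svr: float, r_aa: float, r_da: float, r_psa: float,
                r_dsa: float, r_pia: float, r_dia: float, r_pda: float
                ) -> float:
    """Distal terminal resistance that makes the network DC resistance
    equal the target SVR."""
    x = svr - r_aa
    r_sa_tot = r_psa + r_dsa
    if x <= 0 or x >= r_sa_tot:
        raise InitializationError("SVR closure infeasible: supra-aortic branch "
                                  "cannot carry the required conductance")
    branch2 = 1.0 / (1.0 / x - 1.0 / r_sa_tot)
    y = branch2 - r_da
    r_ia_tot = r_pia + r_dia
    if y <= 0 or y >= r_ia_tot:
        raise InitializationError("SVR closure infeasible: intercostal branch "
                                  "cannot carry the required conductance")
    r_term = 1.0 / (1.0 / y - 1.0 / r_ia_tot)
    r_dda = r_term - r_pda
    if r_dda <= 0:
        raise InitializationError("SVR closure infeasible: R_dda <= 0")
    return r_dda


def peripheral_compliances(indices: ClinicalIndices,
                           branch_means: Tuple[float, float, float],
                           c_aa: float, c_da: float) -> Dict[str, float]:
    """Initial Windkessel compliances.

    Total arterial compliance is SV/PP; the supra-aortic and intercostal
    compliances take the branch mean-flow fraction of the total, and
    C_pda absorbs the remainder (floored at 10% of the total).
    """
    if indices.PP <= 0:
        raise InitializationError("pulse pressure must be > 0")
    c_tot = indices.SV / indices.PP
    q_sa, q_ia, _ = branch_means
    c_psa = c_tot * q_sa / indices.CO
    c_pia = c_tot * q_ia / indices.CO
    c_pda = close_c_pda(c_tot, c_psa, c_pia, c_aa, c_da)
    return {"c_psa": c_psa, "c_pia": c_pia, "c_pda": c_pda, "c_total": c_tot}


def close_c_pda(c_total: float, c_psa: float, c_pia: float,
                c_aa: float, c_da: float) -> float:
    """Terminal compliance closing the total arterial compliance, floored
    at 10% of the total so it stays positive."""
    return max(c_total - (c_psa + c_pia + c_aa + c_da), 0.1 * c_total)


def build_initial_parameters(meas: SubjectMeasurements) -> InitializationReport:
    """Assemble the full stage-one parameter set with provenance tags."""
    indices = compute_indices(meas, rho=LITERATURE_VALUES["rho"])
    d = dict(LITERATURE_VALUES)
    prov = {name: "literature-default" for name in d}

    d["t_cycle"] = meas.T
    # contraction onsets keep their phase within the cycle
    d["onset_la"] = LITERATURE_VALUES["onset_la"] * (
        meas.T / LITERATURE_VALUES["t_cycle"])
    d["a_ao"] = meas.A_ao
    eoa = meas.EOA_av
    if eoa is None:
        eoa = eoa_continuity(net_volume(meas.waveforms["F2"]), meas.VTI_av)
        prov["eoa_av"] = "formula"
    else:
        prov["eoa_av"] = "measured-fixed"
    if not eoa < meas.A_ao:
        raise InitializationError("EOA_av must be smaller than A_ao")
    d["eoa_av"] = eoa
    for name in ("t_cycle", "a_ao"):
        prov[name] = "measured-fixed"

    v0, clamped = v0_lv_single_beat(meas, indices)
    # floor keeps the +/-10% optimization interval well-posed when the
    # single-beat estimate clamps at zero
    d["v0_lv"] = max(v0, 0.5)
    prov["v0_lv"] = "formula"
    d["e_max_lv"] = emax_lv_initial(indices.Pes_LV, meas.ESV, v0)
    prov["e_max_lv"] = "formula"

    branch = branch_mean_flows(meas.waveforms["F3"], meas.waveforms["F4"],
                               meas.waveforms["F5"])
    res = systemic_resistances(indices, branch, d["r_aa"], d["r_da"],
                               d["l_aa"], d["c_aa"], d["l_da"], d["c_da"])
    comp = peripheral_compliances(indices, branch, d["c_aa"], d["c_da"])
    for k in ("r_psa", "r_pia", "r_pda", "r_dsa", "r_dia"):
        d[k] = res[k]
        prov[k] = "formula"
    d["r_dda"] = res["r_dda"]
    prov["r_dda"] = "closure"
    for k in ("c_psa", "c_pia"):
        d[k] = comp[k]
        prov[k] = "formula"
    d["c_pda"] = comp["c_pda"]
    prov["c_pda"] = "closure"

    params0 = AvatarParameters.from_dict(d, roles=default_roles())
    params0.validate()
    roles = params0.roles
    for name, role in roles.items():
        if role == "narrow":
            prov[name] = "narrow" if prov[name] == "literature-default" else prov[name]
    return InitializationReport(
        params0=params0, provenance=prov, indices=indices,
        svr_target=indices.SVR, c_total_target=comp["c_total"],
        v0_clamped=clamped,
    )
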