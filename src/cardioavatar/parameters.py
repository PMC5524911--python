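"""Parameter types for the lumped-parameter circulation model.

The model is described by 50 parameters: 6 for the pulmonary venous
system, 25 for the heart and valves, 17 for the systemic arterial
system, plus the cardiac cycle length ``T`` and the blood density
``rho``.  Every parameter has a canonical snake_case name (see
:data:`PARAM_NAMES`) and a role tag that controls how the two-stage
personalization treats it:

``fixed``
    never optimized (measured geometry/timing and the pulmonary set).
``closure``
    recomputed from constraints (``r_dda`` closes the DC resistance to
    the systemic vascular resistance, ``c_pda`` closes the total
    arterial compliance).
``narrow``
    optimized within +/-10% of the initial estimate.
``free``
    optimized within class-dependent bounds.
"""

from __future__ import annotations

import json

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "ChamberParams",
    "MitralValveParams",
    "AorticValveParams",
    "VesselSegmentParams",
    "WindkesselParams",
    "PulmonaryVenousParams",
    "AvatarParameters",
    "PARAM_NAMES",
    "FIXED_PARAMS",
    "CLOSURE_PARAMS",
    "NARROW_PARAMS",
    "FREE_PARAMS",
    "OPTIMIZED_PARAMS",
    "PARAM_CLASS",
    "literature_parameters",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass
class ChamberParams:
    """Time-varying elastance chamber (atrium or ventricle).

    Elastance follows a double-Hill activation/relaxation product scaled
    so that its maximum over one cycle equals ``E_max``; ``Ks`` adds a
    flow-dependent source resistance and ``R_visc`` a linear viscous
    loss at the chamber outlet.
    """

    E_min: float
    E_max: float
    V0: float
    m1: float
    m2: float
    alpha1: float
    alpha2: float
    Ks: float
    R_visc: float
    onset: float

    def validate(self, label: str = "chamber") -> None:
        if not (self.E_max >= self.E_min > 0):
            raise ParameterError(f"{label}: need E_max >= E_min > 0")
        if self.V0 < 0:
            raise ParameterError(f"{label}: V0 must be >= 0")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ParameterError(f"{label}: m1, m2 must be > 0")
        if not (0 < self.alpha1 < 1 and 0 < self.alpha2 < 1):
            raise ParameterError(f"{label}: alpha1, alpha2 must be in (0, 1)")
        if self.Ks < 0 or self.R_visc < 0:
            raise ParameterError(f"{label}: Ks, R_visc must be >= 0")


@dataclass
class MitralValveParams:
    R_mv: float
    L_mv: float

    def validate(self) -> None:
        if self.R_mv <= 0 or self.L_mv <= 0:
            raise ParameterError("mitral valve: R_mv, L_mv must be > 0")


@dataclass
class AorticValveParams:
    EOA_av: float
    A_ao: float
    L_av: float

    def validate(self) -> None:
        if not (0 < self.EOA_av < self.A_ao):
            raise ParameterError("aortic valve: need 0 < EOA_av < A_ao")
        if self.L_av <= 0:
            raise ParameterError("aortic valve: L_av must be > 0")


@dataclass
class VesselSegmentParams:
    """Series R-L segment with a viscoelastic (Rv in series with C) store."""

    R: float
    L: float
    Rv: float
    C: float

    def validate(self, label: str = "segment") -> None:
        if min(self.R, self.L, self.Rv, self.C) <= 0:
            raise ParameterError(f"{label}: all of R, L, Rv, C must be > 0")


@dataclass
class WindkesselParams:
    """Three-element Windkessel: proximal R, then C parallel to distal R."""

    Rp: float
    Rd: float
    Cp: float

    def validate(self, label: str = "windkessel") -> None:
        if min(self.Rp, self.Rd, self.Cp) <= 0:
            raise ParameterError(f"{label}: all of Rp, Rd, Cp must be > 0")


@dataclass
class PulmonaryVenousParams:
    P_pu: float
    R_pu: float
    R_pv: float
    L_pv: float
    R_pvc: float
    C_pvc: float

    def validate(self) -> None:
        if min(self.P_pu, self.R_pu, self.R_pv, self.L_pv, self.R_pvc, self.C_pvc) <= 0:
            raise ParameterError("pulmonary venous: all values must be > 0")


# Canonical flat ordering used by the numeric core, the optimizer and all
# file formats.  Do not reorder.
PARAM_NAMES: Tuple[str, ...] = (
    # left atrium
    "e_min_la", "e_max_la", "v0_la", "m1_la", "m2_la",
    "alpha1_la", "alpha2_la", "ks_la", "r_visc_la", "onset_la",
    # left ventricle
    "e_min_lv", "e_max_lv", "v0_lv", "m1_lv", "m2_lv",
    "alpha1_lv", "alpha2_lv", "ks_lv", "r_visc_lv", "onset_lv",
    # valves
    "r_mv", "l_mv",
    "eoa_av", "a_ao", "l_av",
    # ascending aorta segment
    "r_aa", "l_aa", "r_aav", "c_aa",
    # descending/abdominal aorta segment
    "r_da", "l_da", "r_dav", "c_da",
    # supra-aortic windkessel
    "r_psa", "r_dsa", "c_psa",
    # intercostal windkessel
    "r_pia", "r_dia", "c_pia",
    # terminal abdominal windkessel
    "r_pda", "r_dda", "c_pda",
    # pulmonary venous system
    "p_pu", "r_pu", "r_pv", "l_pv", "r_pvc", "c_pvc",
    # global
    "t_cycle", "rho",
)

PARAM_INDEX: Dict[str, int] = {n: i for i, n in enumerate(PARAM_NAMES)}

# Role partition.  The fixed set holds measured geometry/timing, blood
# density and the literature-pinned pulmonary vessel parameters (the
# pulmonary pressure source p_pu stays free).
FIXED_PARAMS: Tuple[str, ...] = (
    "eoa_av", "a_ao", "r_psa", "r_pia", "r_pda", "t_cycle", "rho",
    "r_pu", "r_pv", "l_pv", "r_pvc", "c_pvc",
)
CLOSURE_PARAMS: Tuple[str, ...] = ("r_dda", "c_pda")
NARROW_PARAMS: Tuple[str, ...] = ("e_max_lv", "v0_lv", "r_dia", "r_dsa")
FREE_PARAMS: Tuple[str, ...] = tuple(
    n for n in PARAM_NAMES
    if n not in FIXED_PARAMS + CLOSURE_PARAMS + NARROW_PARAMS
)
# Parameters the stage-two optimizer actually moves (32 free + 4 narrow).
OPTIMIZED_PARAMS: Tuple[str, ...] = tuple(
    n for n in PARAM_NAMES if n in FREE_PARAMS + NARROW_PARAMS
)

assert len(FREE_PARAMS) == 32
assert len(OPTIMIZED_PARAMS) == 36

# Bound classes used by the optimizer: resistances [p/2, 2p], inertances
# [p/5, 5p], compliances [p/6, 6p], heart-chamber parameters [p/2, 2p].
_CLASS_BY_PREFIX = [
    ("r_", "resistance"),
    ("l_", "inertance"),
    ("c_", "compliance"),
]


def _param_class(name: str) -> str:
    if name in ("onset_la", "onset_lv"):
        return "onset"
    if name.endswith("_la") or name.endswith("_lv"):
        return "heart"
    for prefix, cls in _CLASS_BY_PREFIX:
        if name.startswith(prefix):
            return cls
    if name == "p_pu":
        return "heart"  # pressure source: conservative [p/2, 2p] interval
    return "heart"


PARAM_CLASS: Dict[str, str] = {n: _param_class(n) for n in PARAM_NAMES}


@dataclass
class AvatarParameters:
    """Complete model description plus per-parameter role tags."""

    la: ChamberParams
    lv: ChamberParams
    mv: MitralValveParams
    av: AorticValveParams
    asc_aorta: VesselSegmentParams
    desc_aorta: VesselSegmentParams
    wk_sa: WindkesselParams
    wk_ia: WindkesselParams
    wk_da: WindkesselParams
    pulm: PulmonaryVenousParams
    T: float
    rho: float = 1.06
    roles: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.roles:
            self.roles = default_roles()

    def validate(self) -> None:
        if self.T <= 0:
            raise ParameterError("T must be > 0")
        if self.rho <= 0:
            raise ParameterError("rho must be > 0")
        self.la.validate("la")
        self.lv.validate("lv")
        self.mv.validate()
        self.av.validate()
        self.asc_aorta.validate("ascending aorta")
        self.desc_aorta.validate("descending aorta")
        self.wk_sa.validate("supra-aortic windkessel")
        self.wk_ia.validate("intercostal windkessel")
        self.wk_da.validate("terminal windkessel")
        self.pulm.validate()
        closures = [n for n, r in self.roles.items() if r == "closure"]
        if sorted(closures) != sorted(CLOSURE_PARAMS):
            raise ParameterError(f"closure set must be {CLOSURE_PARAMS}, got {closures}")

    # -- flat-vector interface ------------------------------------------------

    def to_vector(self) -> np.ndarray:
        d = self.to_dict()
        return np.array([d[n] for n in PARAM_NAMES], dtype=float)

    def to_dict(self) -> Dict[str, float]:
        la, lv = self.la, self.lv
        return {
            "e_min_la": la.E_min, "e_max_la": la.E_max, "v0_la": la.V0,
            "m1_la": la.m1, "m2_la": la.m2, "alpha1_la": la.alpha1,
            "alpha2_la": la.alpha2, "ks_la": la.Ks, "r_visc_la": la.R_visc,
            "onset_la": la.onset,
            "e_min_lv": lv.E_min, "e_max_lv": lv.E_max, "v0_lv": lv.V0,
            "m1_lv": lv.m1, "m2_lv": lv.m2, "alpha1_lv": lv.alpha1,
            "alpha2_lv": lv.alpha2, "ks_lv": lv.Ks, "r_visc_lv": lv.R_visc,
            "onset_lv": lv.onset,
            "r_mv": self.mv.R_mv, "l_mv": self.mv.L_mv,
            "eoa_av": self.av.EOA_av, "a_ao": self.av.A_ao, "l_av": self.av.L_av,
            "r_aa": self.asc_aorta.R, "l_aa": self.asc_aorta.L,
            "r_aav": self.asc_aorta.Rv, "c_aa": self.asc_aorta.C,
            "r_da": self.desc_aorta.R, "l_da": self.desc_aorta.L,
            "r_dav": self.desc_aorta.Rv, "c_da": self.desc_aorta.C,
            "r_psa": self.wk_sa.Rp, "r_dsa": self.wk_sa.Rd, "c_psa": self.wk_sa.Cp,
            "r_pia": self.wk_ia.Rp, "r_dia": self.wk_ia.Rd, "c_pia": self.wk_ia.Cp,
            "r_pda": self.wk_da.Rp, "r_dda": self.wk_da.Rd, "c_pda": self.wk_da.Cp,
            "p_pu": self.pulm.P_pu, "r_pu": self.pulm.R_pu, "r_pv": self.pulm.R_pv,
            "l_pv": self.pulm.L_pv, "r_pvc": self.pulm.R_pvc, "c_pvc": self.pulm.C_pvc,
            "t_cycle": self.T, "rho": self.rho,
        }

    @classmethod
    def from_dict(cls, d: Dict[str, float], roles: Dict[str, str] | None = None
                  ) -> "AvatarParameters":
        missing = [n for n in PARAM_NAMES if n not in d]
        if missing:
            raise ParameterError(f"missing parameters: {missing}")
        return cls(
            la=ChamberParams(d["e_min_la"], d["e_max_la"], d["v0_la"], d["m1_la"],
                             d["m2_la"], d["alpha1_la"], d["alpha2_la"], d["ks_la"],
                             d["r_visc_la"], d["onset_la"]),
            lv=ChamberParams(d["e_min_lv"], d["e_max_lv"], d["v0_lv"], d["m1_lv"],
                             d["m2_lv"], d["alpha1_lv"], d["alpha2_lv"], d["ks_lv"],
                             d["r_visc_lv"], d["onset_lv"]),
            mv=MitralValveParams(d["r_mv"], d["l_mv"]),
            av=AorticValveParams(d["eoa_av"], d["a_ao"], d["l_av"]),
            asc_aorta=VesselSegmentParams(d["r_aa"], d["l_aa"], d["r_aav"], d["c_aa"]),
            desc_aorta=VesselSegmentParams(d["r_da"], d["l_da"], d["r_dav"], d["c_da"]),
            wk_sa=WindkesselParams(d["r_psa"], d["r_dsa"], d["c_psa"]),
            wk_ia=WindkesselParams(d["r_pia"], d["r_dia"], d["c_pia"]),
            wk_da=WindkesselParams(d["r_pda"], d["r_dda"], d["c_pda"]),
            pulm=PulmonaryVenousParams(d["p_pu"], d["r_pu"], d["r_pv"], d["l_pv"],
                                       d["r_pvc"], d["c_pvc"]),
            T=d["t_cycle"],
            rho=d["rho"],
            roles=dict(roles) if roles else default_roles(),
        )

    @classmethod
    def from_vector(cls, v: np.ndarray, roles: Dict[str, str] | None = None
                    ) -> "AvatarParameters":
        v = np.asarray(v, dtype=float)
        if v.shape != (len(PARAM_NAMES),):
            raise ParameterError(f"expected vector of length {len(PARAM_NAMES)}")
        return cls.from_dict(dict(zip(PARAM_NAMES, v.tolist())), roles)

    def replace(self, **updates: float) -> "AvatarParameters":
        """Return a copy with named parameters replaced."""
        d = self.to_dict()
        for k, val in updates.items():
            if k not in d:
                raise ParameterError(f"unknown parameter {k!r}")
            d[k] = float(val)
        return AvatarParameters.from_dict(d, roles=self.roles)

    # -- serialization --------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {"schema": "cardioavatar-parameters-1",
                   "values": self.to_dict(), "roles": self.roles}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "AvatarParameters":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.from_dict(payload["values"], roles=payload.get("roles"))


def default_roles() -> Dict[str, str]:
    roles = {}
    for n in PARAM_NAMES:
        if n in FIXED_PARAMS:
            roles[n] = "fixed"
        elif n in CLOSURE_PARAMS:
            roles[n] = "closure"
        elif n in NARROW_PARAMS:
            roles[n] = "narrow"
        else:
            roles[n] = "free"
    return roles


# Healthy-adult literature values used both as population defaults and as
# the centre of the virtual-subject generator.
LITERATURE_VALUES: Dict[str, float] = {
    "e_min_la": 0.08, "e_max_la": 0.17, "v0_la": 3.0, "m1_la": 1.32,
    "m2_la": 13.1, "alpha1_la": 0.11, "alpha2_la": 0.18, "ks_la": 10e-9,
    "r_visc_la": 1e-4, "onset_la": 0.85,
    "e_min_lv": 0.08, "e_max_lv": 3.0, "v0_lv": 10.0, "m1_lv": 1.32,
    "m2_lv": 27.4, "alpha1_lv": 0.269, "alpha2_lv": 0.452, "ks_lv": 4e-9,
    "r_visc_lv": 1e-4, "onset_lv": 0.0,
    "r_mv": 3.75e-3, "l_mv": 2e-4,
    "eoa_av": 1.69, "a_ao": 5.0, "l_av": 4e-4,
    "r_aa": 0.04, "l_aa": 5e-4, "r_aav": 0.01, "c_aa": 0.1,
    "r_da": 0.04, "l_da": 5e-4, "r_dav": 0.01, "c_da": 0.1,
    "r_psa": 0.05, "r_dsa": 3.9, "c_psa": 0.6,
    "r_pia": 0.05, "r_dia": 3.0, "c_pia": 0.93,
    "r_pda": 0.05, "r_dda": 1.2, "c_pda": 2.0,
    "p_pu": 7.4, "r_pu": 0.01, "r_pv": 2e-3, "l_pv": 5e-4,
    "r_pvc": 0.01, "c_pvc": 4.0,
    "t_cycle": 0.9, "rho": 1.06,
}


def literature_parameters(**overrides: float) -> AvatarParameters:
    """Healthy-adult default parameter set (optionally overridden)."""
    d = dict(LITERATURE_VALUES)
    for k, v in overrides.items():
        if k not in d:
            raise ParameterError(f"unknown parameter {k!r}")
        d[k] = float(v)
    p = AvatarParameters.from_dict(d)
    p.validate()
    return p
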