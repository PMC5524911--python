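"""Measurement-side data model and clinical index calculators.

A subject bundle holds five volumetric flow waveforms (mitral valve F1,
aortic valve F2, distal ascending aorta F3, aortic arch F4, abdominal
aorta F5; one cardiac cycle each, frame 1 at the R-wave), brachial cuff
pressures, cycle length, LV end-systolic volume and aortic valve/root
geometry.  Waveforms are stored as CSV (columns ``t_s``, ``q_ml_s``)
with a JSON metadata file.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LOCATIONS",
    "FlowWaveform",
    "VelocityPlane",
    "SubjectMeasurements",
    "ClinicalIndices",
    "plane_flow",
    "net_volume",
    "time_average",
    "eoa_continuity",
    "map_from_cuff",
    "pes_lv",
    "branch_mean_flows",
    "compute_indices",
]

LOCATIONS = ("F1", "F2", "F3", "F4", "F5")


class MeasurementError(ValueError):
    pass


@dataclass
class FlowWaveform:
    """One cycle of volumetric flow at a named analysis location."""

    location: str
    t: np.ndarray     # s, strictly increasing, spanning one cycle
    q: np.ndarray     # mL/s
    period: float     # cardiac cycle length the samples span, s

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.location not in LOCATIONS:
            raise MeasurementError(f"unknown location {self.location!r}")
        if self.t.ndim != 1 or self.t.shape != self.q.shape:
            raise MeasurementError("t and q must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise MeasurementError("waveform times must be strictly increasing")
        if not (np.all(np.isfinite(self.t)) and np.all(np.isfinite(self.q))):
            raise MeasurementError("waveform contains non-finite values")
        if self.t[-1] >= self.period + 1e-12:
            raise MeasurementError("waveform times exceed the stated period")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class VelocityPlane:
    """Through-plane velocity samples on a pixel grid (for retrospective
    plane-based flow quantification)."""

    v_perp: np.ndarray    # cm/s
    pixel_area: float     # cm^2
    mask: np.ndarray      # boolean inclusion grid

    def __post_init__(self) -> None:
        self.v_perp = np.asarray(self.v_perp, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.v_perp.shape != self.mask.shape:
            raise MeasurementError("velocity grid and mask must be congruent")
        if self.pixel_area <= 0:
            raise MeasurementError("pixel_area must be > 0")


@dataclass
class SubjectMeasurements:
    """The non-invasive bundle a personalization consumes."""

    waveforms: Dict[str, FlowWaveform]
    SBP: float
    DBP: float
    T: float
    ESV: float
    A_ao: float
    VTI_av: Optional[float] = None
    EOA_av: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [loc for loc in LOCATIONS if loc not in self.waveforms]
        if missing:
            raise MeasurementError(f"missing waveforms: {missing}")
        if not (self.SBP > self.DBP > 0):
            raise MeasurementError("need SBP > DBP > 0")
        if self.T <= 0 or self.ESV <= 0 or self.A_ao <= 0:
            raise MeasurementError("T, ESV, A_ao must be > 0")
        if self.VTI_av is None and self.EOA_av is None:
            raise MeasurementError("either VTI_av or EOA_av is required")
        for w in self.waveforms.values():
            if abs(w.period - self.T) > 0.02 * self.T:
                raise MeasurementError(
                    f"waveform {w.location} period differs from T by more than 2%")

    @property
    def HR(self) -> float:
        """Heart rate in bpm."""
        return 60.0 / self.T

    # -- I/O ------------------------------------------------------------------

    def save(self, directory) -> Path:
        """Write waveform CSVs plus ``subject.json``; returns the JSON path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        files = {}
        for loc in LOCATIONS:
            w = self.waveforms[loc]
            fname = f"waveform_{loc}.csv"
            pd.DataFrame({"t_s": w.t, "q_ml_s": w.q}).to_csv(
                directory / fname, index=False)
            files[loc] = fname
        meta = {
            "schema": "cardioavatar-subject-1",
            "SBP_mmHg": self.SBP, "DBP_mmHg": self.DBP,
            "T_s": self.T, "ESV_mL": self.ESV, "A_ao_cm2": self.A_ao,
            "VTI_av_cm": self.VTI_av, "EOA_av_cm2": self.EOA_av,
            "waveform_files": files,
        }
        path = directory / "subject.json"
        with open(path, "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        return path

    @classmethod
    def load(cls, json_path) -> "SubjectMeasurements":
        json_path = Path(json_path)
        with open(json_path) as fh:
            meta = json.load(fh)
        waveforms = {}
        for loc in LOCATIONS:
            fname = meta["waveform_files"].get(loc)
            if fname is None:
                raise MeasurementError(f"subject file lists no waveform for {loc}")
            fpath = json_path.parent / fname
            if not fpath.exists():
                raise MeasurementError(f"waveform file for {loc} not found: {fpath}")
            df = pd.read_csv(fpath)
            waveforms[loc] = FlowWaveform(loc, df["t_s"].to_numpy(),
                                          df["q_ml_s"].to_numpy(),
                                          period=meta["T_s"])
        return cls(waveforms=waveforms, SBP=meta["SBP_mmHg"], DBP=meta["DBP_mmHg"],
                   T=meta["T_s"], ESV=meta["ESV_mL"], A_ao=meta["A_ao_cm2"],
                   VTI_av=meta.get("VTI_av_cm"), EOA_av=meta.get("EOA_av_cm2"))


@dataclass
class ClinicalIndices:
    MAP: float
    PP: float
    CO: float
    SV: float
    EF: float
    SVR: float
    Pes_LV: float
    dPav_max: float


def plane_flow(plane: VelocityPlane) -> float:
    """Volumetric flow through an analysis plane: sum over masked pixels
    of through-plane velocity times pixel area (cm^3/s = mL/s)."""
    if not plane.mask.any():
        warnings.warn("plane mask is empty; returning zero flow")
        return 0.0
    return float(np.sum(plane.v_perp[plane.mask]) * plane.pixel_area)


def _wrap(w: FlowWaveform) -> Tuple[np.ndarray, np.ndarray]:
    """Append the periodic wrap sample closing the cycle."""
    t = np.append(w.t, w.t[0] + w.period)
    q = np.append(w.q, w.q[0])
    return t, q


def net_volume(w: FlowWaveform) -> float:
    """Trapezoidal time integral of flow over the cycle, with periodic
    wrap of the last interval (mL)."""
    t, q = _wrap(w)
    return float(np.trapezoid(q, t))


def time_average(w: FlowWaveform) -> float:
    """Cycle-averaged flow (mL/s)."""
    return net_volume(w) / w.period


def eoa_continuity(SV: float, VTI_av: float) -> float:
    """Continuity-equation effective orifice area: SV / VTI (mL/cm = cm^2)."""
    if VTI_av <= 0:
        raise MeasurementError("VTI_av must be > 0")
    if SV < 0:
        raise MeasurementError("SV must be >= 0")
    return SV / VTI_av


def map_from_cuff(SBP: float, DBP: float, HR: float) -> float:
    """Mean arterial pressure from cuff SBP/DBP with the heart-rate
    dependent form factor: DBP + [1/3 + HR*0.0012] * (SBP - DBP)."""
    if SBP < DBP:
        raise MeasurementError("need SBP >= DBP")
    if HR < 0:
        raise MeasurementError("HR must be >= 0")
    return DBP + (1.0 / 3.0 + HR * 0.0012) * (SBP - DBP)


def pes_lv(SBP: float, dPav_max: float) -> float:
    """End-systolic LV pressure estimate: 0.9 * (SBP + peak transaortic
    gradient)."""
    if SBP < 0 or dPav_max < 0:
        raise MeasurementError("inputs must be >= 0")
    return 0.9 * (SBP + dPav_max)


def branch_mean_flows(F3: FlowWaveform, F4: FlowWaveform, F5: FlowWaveform
                      ) -> Tuple[float, float, float]:
    """Mean flows into the supra-aortic, intercostal and terminal beds,
    from differences of the aortic plane means."""
    m3, m4, m5 = time_average(F3), time_average(F4), time_average(F5)
    q_sa, q_ia, q_term = m3 - m4, m4 - m5, m5
    if min(q_sa, q_ia, q_term) <= 0:
        raise MeasurementError(
            f"non-positive branch mean flow (sa={q_sa:.3g}, ia={q_ia:.3g}, "
            f"term={q_term:.3g}); measurements are inconsistent")
    return q_sa, q_ia, q_term


def _aortic_gradient_peak(meas: SubjectMeasurements, rho: float) -> float:
    """Peak transaortic gradient from the measured F2 peak (steady term
    only; dQ/dt = 0 at the peak)."""
    from .model import aortic_gradient
    from .parameters import AorticValveParams

    eoa = meas.EOA_av
    if eoa is None:
        sv = net_volume(meas.waveforms["F2"])
        eoa = eoa_continuity(sv, meas.VTI_av)
    av = AorticValveParams(EOA_av=eoa, A_ao=meas.A_ao, L_av=1e-4)
    q_peak = float(np.max(meas.waveforms["F2"].q))
    return aortic_gradient(q_peak, 0.0, av, rho)


def compute_indices(meas: SubjectMeasurements, rho: float = 1.06) -> ClinicalIndices:
    """Derive the clinical indices a personalization needs.

    SV is defined as the time integral of the aortic-valve flow (F2);
    EF uses EDV = ESV + SV.
    """
    sv = net_volume(meas.waveforms["F2"])
    if sv <= 0:
        raise MeasurementError("non-positive stroke volume from F2")
    co = sv / meas.T
    mean_ap = map_from_cuff(meas.SBP, meas.DBP, meas.HR)
    dpav = _aortic_gradient_peak(meas, rho)
    return ClinicalIndices(
        MAP=mean_ap,
        PP=meas.SBP - meas.DBP,
        CO=co,
        SV=sv,
        EF=sv / (meas.ESV + sv),
        SVR=mean_ap / co,
        Pes_LV=pes_lv(meas.SBP, dpav),
        dPav_max=dpav,
    )
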