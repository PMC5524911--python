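"""Virtual-subject generation.

Emulates the measurement products a real study would provide: a
ground-truth parameter set sampled around healthy-adult literature
values, model-simulated flow waveforms at F1-F5 resampled to ~40 frames
per cycle with additive Gaussian noise, cuff pressures as the extrema of
the simulated aortic root pressure, ESV as the minimum simulated LV
volume, and an aortic-valve velocity-time integral consistent with the
continuity equation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurements import FlowWaveform, SubjectMeasurements, VelocityPlane
from .model import extract_periodic_cycle, simulate
from .parameters import (FIXED_PARAMS, LITERATURE_VALUES, AvatarParameters,
                         PARAM_NAMES)

__all__ = [
    "VirtualSubject",
    "sample_virtual_parameters",
    "generate_measurements",
    "make_velocity_plane",
]

# Cycle-length range of the emulated population (heart rate 55-82 bpm).
T_RANGE = (0.73, 1.09)


@dataclass
class VirtualSubject:
    truth: AvatarParameters
    meas: SubjectMeasurements
    noise_sd: float
    n_frames: int
    seed: int


def sample_virtual_parameters(seed: int, jitter: float = 0.15
                              ) -> AvatarParameters:
    """Draw a ground-truth parameter set around the literature values.

    Non-fixed positive parameters are drawn log-uniformly within a
    factor [1/(1+jitter), 1+jitter] of their literature value; the fixed
    set stays at literature values; T is uniform in the population
    heart-rate range; contraction onsets are handled additively (the LV
    onset's literature value is 0) and the LA onset is rescaled with T
    so the atrial kick keeps its phase within the cycle.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    d = dict(LITERATURE_VALUES)
    if jitter > 0:
        t = float(rng.uniform(*T_RANGE))
    else:
        t = d["t_cycle"]
    span = np.log(1.0 + jitter)
    for name in PARAM_NAMES:
        if name in FIXED_PARAMS or name in ("onset_la", "onset_lv"):
            continue
        u = float(rng.uniform(-1.0, 1.0))
        d[name] = d[name] * float(np.exp(u * span))
    d["t_cycle"] = t
    # onsets: keep phase relative to the cycle; jitter additively
    scale = t / LITERATURE_VALUES["t_cycle"]
    d["onset_la"] = (LITERATURE_VALUES["onset_la"] * scale
                     + float(rng.uniform(-1.0, 1.0)) * jitter * 0.1 * t)
    d["onset_lv"] = float(rng.uniform(-1.0, 1.0)) * jitter * 0.2
    p = AvatarParameters.from_dict(d)
    p.validate()
    return p


def generate_measurements(truth: AvatarParameters, noise_sd: float = 1.0,
                          n_frames: int = 40, seed: int = 0,
                          round_cuff: bool = False, duration: float = 20.0,
                          dt: float = 1e-3) -> SubjectMeasurements:
    """Simulate the truth and sample the measurement bundle from its
    final (periodic) cycle."""
    sim = simulate(truth, duration=duration, dt=dt)
    cycle = extract_periodic_cycle(sim, truth.T, align_to_cycle_start=True)

    # periodicity guard: LV volume must close over the final cycle
    sv = float(np.trapezoid(cycle.F2, cycle.t))
    dv = abs(cycle.V_LV[-1] - cycle.V_LV[0])
    if sv <= 0 or dv > 0.02 * max(sv, 1.0):
        raise RuntimeError("simulation did not reach a periodic regime")

    rng = np.random.default_rng(seed)
    frames = np.arange(n_frames) * truth.T / n_frames
    waveforms = {}
    for loc, q in zip(("F1", "F2", "F3", "F4", "F5"), cycle.flows()):
        qs = np.interp(frames, cycle.t, q)
        qs = qs + rng.normal(0.0, noise_sd, size=n_frames)
        waveforms[loc] = FlowWaveform(loc, frames, qs, period=truth.T)

    sbp = float(np.max(cycle.P_ao))
    dbp = float(np.min(cycle.P_ao))
    if round_cuff:
        sbp, dbp = round(sbp), round(dbp)
    esv = float(np.min(cycle.V_LV))

    w2 = waveforms["F2"]
    sv_sampled = float(np.trapezoid(np.append(w2.q, w2.q[0]),
                                    np.append(w2.t, truth.T)))
    vti = sv_sampled / truth.av.EOA_av

    return SubjectMeasurements(
        waveforms=waveforms, SBP=sbp, DBP=dbp, T=truth.T, ESV=esv,
        A_ao=truth.av.A_ao, VTI_av=vti,
    )


def make_virtual_subject(seed: int, jitter: float = 0.15,
                         noise_sd: float = 1.0, n_frames: int = 40,
                         round_cuff: bool = False) -> VirtualSubject:
    """Sample a truth and generate its measurement bundle (noise seed is
    derived from the subject seed)."""
    truth = sample_virtual_parameters(seed, jitter=jitter)
    meas = generate_measurements(truth, noise_sd=noise_sd, n_frames=n_frames,
                                 seed=seed + 10_000, round_cuff=round_cuff)
    return VirtualSubject(truth=truth, meas=meas, noise_sd=noise_sd,
                          n_frames=n_frames, seed=seed)


def make_velocity_plane(profile: str, peak_v: float, radius_px: int,
                        pixel_area: float) -> VelocityPlane:
    """Synthetic circular analysis plane with a uniform or parabolic
    (Poiseuille) through-plane velocity profile."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    n = 2 * radius_px + 1
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = ((xx - radius_px) ** 2 + (yy - radius_px) ** 2) / radius_px ** 2
    mask = r2 <= 1.0
    if profile == "uniform":
        v = np.full((n, n), peak_v, dtype=float)
    elif profile == "parabolic":
        v = peak_v * (1.0 - r2)
    else:
        raise ValueError("profile must be 'uniform' or 'parabolic'")
    v[~mask] = 0.0
    return VelocityPlane(v_perp=v, pixel_area=pixel_area, mask=mask)
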