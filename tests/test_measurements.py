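import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioavatar.measurements import (FlowWaveform, MeasurementError,
                                       SubjectMeasurements, VelocityPlane,
                                       branch_mean_flows, compute_indices,
                                       eoa_continuity, map_from_cuff,
                                       net_volume, pes_lv, plane_flow,
                                       time_average)
from cardioavatar.synthetic import make_velocity_plane


def _wave(loc, q, T=0.9, n=None):
    q = np.asarray(q, dtype=float)
    n = len(q)
    t = np.arange(n) * T / n
    return FlowWaveform(loc, t, q, period=T)


class TestPlaneFlow:
    def test_empty_mask_warns_and_returns_zero(self):
        plane = VelocityPlane(np.ones((4, 4)), 0.1, np.zeros((4, 4), bool))
        with pytest.warns(UserWarning):
            assert plane_flow(plane) == 0.0

    def test_hand_value(self):
        # 10 pixels at 100 cm/s through 0.0784 cm^2 pixels -> 78.4 mL/s
        v = np.zeros((5, 5))
        mask = np.zeros((5, 5), bool)
        v.flat[:10] = 100.0
        mask.flat[:10] = True
        plane = VelocityPlane(v, 0.0784, mask)
        assert plane_flow(plane) == pytest.approx(78.4)

    def test_antisymmetric_cancellation(self):
        v = np.array([[50.0, -50.0]])
        plane = VelocityPlane(v, 0.1, np.ones((1, 2), bool))
        assert plane_flow(plane) == 0.0

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 5.0))
    def test_linear_in_velocity(self, scale):
        plane = make_velocity_plane("uniform", 80.0, 6, 0.0784)
        scaled = VelocityPlane(plane.v_perp * scale, plane.pixel_area,
                               plane.mask)
        assert plane_flow(scaled) == pytest.approx(scale * plane_flow(plane))

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(6, 6)) * 50
        m1 = np.zeros((6, 6), bool)
        m2 = np.zeros((6, 6), bool)
        m1[:3] = True
        m2[3:] = True
        full = plane_flow(VelocityPlane(v, 0.1, m1 | m2))
        assert full == pytest.approx(
            plane_flow(VelocityPlane(v, 0.1, m1))
            + plane_flow(VelocityPlane(v, 0.1, m2)))


class TestNetVolume:
    def test_constant_flow(self):
        w = _wave("F2", np.full(40, 100.0), T=0.9)
        assert net_volume(w) == pytest.approx(90.0)

    def test_full_period_sinusoid(self):
        n, T = 400, 0.8
        t = np.arange(n) * T / n
        w = FlowWaveform("F1", t, np.sin(2 * np.pi * t / T), period=T)
        assert net_volume(w) == pytest.approx(0.0, abs=1e-9)

    def test_analytic_pulse_oracle(self):
        # closed form: integral of q0*sin^2(pi t/T) over [0, T] = q0*T/2
        n, T, q0 = 2000, 0.9, 300.0
        t = np.arange(n) * T / n
        w = FlowWaveform("F2", t, q0 * np.sin(np.pi * t / T) ** 2, period=T)
        assert net_volume(w) == pytest.approx(q0 * T / 2, rel=1e-3)

    def test_nonmonotone_time_rejected(self):
        with pytest.raises(MeasurementError):
            FlowWaveform("F1", np.array([0.0, 0.2, 0.1]), np.zeros(3),
                         period=0.9)


class TestEoaContinuity:
    def test_hand_value(self):
        assert eoa_continuity(80.0, 20.0) == pytest.approx(4.0)

    def test_zero_sv(self):
        assert eoa_continuity(0.0, 20.0) == 0.0

    def test_scale_invariance(self):
        assert eoa_continuity(160.0, 40.0) == eoa_continuity(80.0, 20.0)

    def test_zero_vti_rejected(self):
        with pytest.raises(MeasurementError):
            eoa_continuity(80.0, 0.0)


class TestMapFromCuff:
    def test_degenerate_pulse(self):
        assert map_from_cuff(90.0, 90.0, 60.0) == 90.0

    def test_hand_value(self):
        # DBP + [1/3 + 60*0.0012] * 60 = 60 + 0.4053*60 = 84.32
        assert map_from_cuff(120.0, 60.0, 60.0) == pytest.approx(84.32)

    def test_zero_hr_classic_form(self):
        assert map_from_cuff(120.0, 60.0, 0.0) == pytest.approx(80.0)

    def test_inverted_pressures_rejected(self):
        with pytest.raises(MeasurementError):
            map_from_cuff(60.0, 120.0, 60.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(80, 200), st.floats(40, 79), st.floats(30, 120),
           st.floats(0.1, 10.0))
    def test_monotone_in_each_argument(self, sbp, dbp, hr, eps):
        base = map_from_cuff(sbp, dbp, hr)
        assert map_from_cuff(sbp + eps, dbp, hr) > base
        assert map_from_cuff(sbp, dbp + eps, hr) > base if dbp + eps < sbp \
            else True
        assert map_from_cuff(sbp, dbp, hr + eps) > base


class TestPesLv:
    def test_no_gradient(self):
        assert pes_lv(120.0, 0.0) == pytest.approx(108.0)

    def test_with_gradient(self):
        assert pes_lv(120.0, 10.0) == pytest.approx(117.0)

    def test_exact_ratio(self):
        assert pes_lv(135.0, 7.0) / (135.0 + 7.0) == pytest.approx(0.9)


class TestBranchMeans:
    def test_identical_means_rejected(self):
        f = _wave("F3", np.full(40, 90.0))
        g = _wave("F4", np.full(40, 90.0))
        h = _wave("F5", np.full(40, 40.0))
        with pytest.raises(MeasurementError):
            branch_mean_flows(f, g, h)

    def test_subtraction(self):
        f3 = _wave("F3", np.full(40, 90.0))
        f4 = _wave("F4", np.full(40, 60.0))
        f5 = _wave("F5", np.full(40, 40.0))
        assert branch_mean_flows(f3, f4, f5) == pytest.approx((30.0, 20.0,
                                                               40.0))

    def test_consistent_with_model_outlets(self, lit_params, lit_cycle):
        import cardioavatar.model as m
        T = lit_params.T
        waves = {}
        for loc, q in zip(("F1", "F2", "F3", "F4", "F5"), lit_cycle.flows()):
            t = np.arange(40) * T / 40
            waves[loc] = FlowWaveform(loc, t, np.interp(t, lit_cycle.t, q),
                                      period=T)
        q_sa, q_ia, q_term = branch_mean_flows(waves["F3"], waves["F4"],
                                               waves["F5"])
        outs = m.windkessel_outflows(lit_cycle)
        means = [np.trapezoid(q, lit_cycle.t) / T for q in outs]
        assert q_sa == pytest.approx(means[0], rel=0.05)
        assert q_ia == pytest.approx(means[1], rel=0.05)
        assert q_term == pytest.approx(means[2], rel=0.05)


class TestSubjectBundle:
    def test_roundtrip_io(self, tmp_path, noisefree_subject):
        meas = noisefree_subject.meas
        path = meas.save(tmp_path / "subj")
        loaded = SubjectMeasurements.load(path)
        assert loaded.SBP == pytest.approx(meas.SBP)
        assert loaded.T == meas.T
        for loc in ("F1", "F2", "F3", "F4", "F5"):
            np.testing.assert_allclose(loaded.waveforms[loc].q,
                                       meas.waveforms[loc].q)

    def test_missing_waveform_rejected(self, noisefree_subject):
        meas = noisefree_subject.meas
        partial = {k: v for k, v in meas.waveforms.items() if k != "F3"}
        with pytest.raises(MeasurementError, match="F3"):
            SubjectMeasurements(waveforms=partial, SBP=meas.SBP, DBP=meas.DBP,
                                T=meas.T, ESV=meas.ESV, A_ao=meas.A_ao,
                                VTI_av=meas.VTI_av)

    def test_sv_definition_shared(self, noisefree_subject):
        meas = noisefree_subject.meas
        idx = compute_indices(meas)
        assert idx.SV == pytest.approx(net_volume(meas.waveforms["F2"]))
        assert idx.CO == pytest.approx(idx.SV / meas.T)
        assert 0 < idx.EF < 1
        assert idx.PP == pytest.approx(meas.SBP - meas.DBP)
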