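import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from neovent.mechanics import (
    PatientParams,
    SimConfig,
    VentSettings,
    make_patient,
    pcv_waveform,
    simulate_to_steady_cycle,
)
from neovent.measurement import breath_metrics

from conftest import single_compartment_vt


class TestMakePatient:
    def test_series_parallel_compliance_algebra(self):
        p = make_patient(1.14, 5.0, 1.0, 131.0, 88.0)
        assert p.CL * 1000 == pytest.approx(1.368)
        assert p.Cw * 1000 == pytest.approx(6.84)
        assert p.C1 * 1000 == pytest.approx(0.684)
        assert p.C2 * 1000 == pytest.approx(0.684)
        assert p.Cstat * 1000 == pytest.approx(1.14)
        assert p.Rstat == pytest.approx(131.0 + 44.0)

    def test_compliance_split_index(self):
        p = make_patient(1.14, 5.0, 10.0, 131.0, 88.0)
        assert p.C1 * 1000 == pytest.approx(1.368 * 10 / 11)
        assert p.C2 * 1000 == pytest.approx(1.368 / 11)
        assert p.t1_over_t2 == pytest.approx(10.0, abs=1e-12)
        assert p.Cstat * 1000 == pytest.approx(1.14)

    def test_resistance_split_preserves_static_total(self):
        p = make_patient(1.14, 5.0, 4.0, 131.0, 88.0, mode="resistance-split")
        assert p.C1 == pytest.approx(p.C2)
        assert p.t1_over_t2 == pytest.approx(4.0, abs=1e-12)
        assert p.Rstat == pytest.approx(131.0 + 44.0)

    @pytest.mark.parametrize("field", ["c_total", "cw_over_cl", "t1_over_t2", "rc", "r_periph_each"])
    def test_nonpositive_inputs_rejected_with_field_name(self, field):
        kwargs = dict(c_total=1.14, cw_over_cl=5.0, t1_over_t2=1.0, rc=131.0, r_periph_each=88.0)
        kwargs[field] = 0.0
        with pytest.raises(ValueError, match=field):
            make_patient(**kwargs)

    def test_relabelling_keeps_slow_compartment_first(self):
        p = PatientParams(Rc=131, R1=88, R2=88, C1=0.0002, C2=0.001, Cw=0.007)
        assert p.T1 >= p.T2
        assert p.C1 == pytest.approx(0.001)
        assert p.t1_over_t2 >= 1

    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        c_total=st.floats(0.3, 3.0),
        k=st.floats(1.0, 20.0),
        r=st.floats(1.0, 100.0),
        mode=st.sampled_from(["compliance-split", "resistance-split"]),
    )
    def test_construction_invariants(self, c_total, k, r, mode):
        p = make_patient(c_total, k, r, 131.0, 88.0, mode=mode)
        assert p.Cstat * 1000 == pytest.approx(c_total, rel=1e-9)
        assert p.Cw / p.CL == pytest.approx(k, rel=1e-9)
        assert p.t1_over_t2 == pytest.approx(r, rel=1e-9)
        assert p.Cstat < min(p.CL, p.Cw)


class TestWaveform:
    def test_ramp_plateau_release(self):
        s = VentSettings(RR=50, PIP=25, PEEP=5, IE=(1, 2), rise_time=0.1)
        assert pcv_waveform(s, 0.0) == pytest.approx(5.0)
        assert pcv_waveform(s, 0.05) == pytest.approx(15.0)
        assert pcv_waveform(s, s.Ti - 1e-9) == pytest.approx(25.0)
        assert pcv_waveform(s, s.Ti) == pytest.approx(5.0)

    def test_duty_cycle_average(self):
        s = VentSettings(RR=50, PIP=25, PEEP=5, IE=(1, 2), rise_time=0.0)
        t = np.linspace(0, s.period, 200001)
        assert np.trapezoid(pcv_waveform(s, t), t) / s.period == pytest.approx(35.0 / 3.0, rel=1e-4)

    def test_settings_invariants_enforced(self):
        with pytest.raises(ValueError, match="PIP >= PEEP"):
            VentSettings(RR=50, PIP=4, PEEP=5)
        with pytest.raises(ValueError, match="rise_time"):
            VentSettings(RR=50, PIP=25, PEEP=5, IE=(1, 2), rise_time=0.5)
        with pytest.raises(ValueError, match="RR"):
            VentSettings(RR=0, PIP=25, PEEP=5)


class TestSteadyCycle:
    def test_symmetric_circuit_splits_evenly(self, p3_symmetric, settings_rr50, cfg):
        tr = simulate_to_steady_cycle(p3_symmetric, settings_rr50, cfg)
        assert tr.steady
        np.testing.assert_allclose(tr.V1, tr.V2, rtol=1e-9, atol=1e-15)
        np.testing.assert_allclose(tr.Q1, tr.Q2, rtol=1e-9, atol=1e-12)

    def test_no_driving_pressure_no_tidal_volume(self, p3_symmetric, cfg):
        s = VentSettings(RR=50, PIP=5, PEEP=5, IE=(1, 2), rise_time=0.0)
        tr = simulate_to_steady_cycle(p3_symmetric, s, cfg)
        m = breath_metrics(tr, s)
        assert m.Vt == pytest.approx(0.0, abs=1e-6)
        assert m.WOB_vt == 0.0
        assert "zero tidal volume" in m.warning

    def test_node_flow_conservation(self, p3_symmetric, settings_rr50, cfg):
        p10 = make_patient(1.14, 5.3, 10.0, 131.0, 88.0)
        for p in (p3_symmetric, p10):
            tr = simulate_to_steady_cycle(p, settings_rr50, cfg)
            scale = np.max(np.abs(tr.Q))
            assert np.max(np.abs(tr.Q - (tr.Q1 + tr.Q2))) <= 1e-9 * scale

    def test_single_compartment_equivalence_at_unit_index(self, p3_symmetric, settings_rr50, cfg):
        """At T1/T2 = 1 the circuit reduces exactly to R = Rc + R1/2,
        C = CL*Cw/(CL+Cw); the simulated tidal volume must match the
        first-order closed form to < 0.5%."""
        tr = simulate_to_steady_cycle(p3_symmetric, settings_rr50, cfg)
        m = breath_metrics(tr, settings_rr50)
        vt = single_compartment_vt(20.0, p3_symmetric.Cstat,
                                   p3_symmetric.Rc + p3_symmetric.R1 / 2,
                                   settings_rr50.Ti, settings_rr50.Te) * 1000
        assert m.Vt == pytest.approx(vt, rel=5e-3)

    def test_blocked_compartment_matches_first_order_oracle(self, cfg):
        base = make_patient(1.14, 5.3, 1.0, 131.0, 88.0)
        blocked = PatientParams(Rc=base.Rc, R1=base.R1, R2=1e9,
                                C1=base.C1, C2=base.C2, Cw=base.Cw)
        s = VentSettings(RR=50, PIP=25, PEEP=5, IE=(1, 2), rise_time=0.0)
        tr = simulate_to_steady_cycle(blocked, s, cfg)
        m = breath_metrics(tr, s)
        # after relabelling the open pathway is compartment 2 (R = 88)
        ceq = blocked.C2 * blocked.Cw / (blocked.C2 + blocked.Cw)
        vt = single_compartment_vt(20.0, ceq, blocked.Rc + blocked.R2, s.Ti, s.Te) * 1000
        assert m.Vt == pytest.approx(vt, rel=5e-3)

    def test_periodicity_and_convergence_monotone_in_cycles(self, p3_symmetric, settings_rr50):
        tr = simulate_to_steady_cycle(p3_symmetric, settings_rr50, SimConfig())
        for v in (tr.V1, tr.V2):
            assert abs(v[-1] - v[0]) / np.max(np.abs(v)) <= 1e-6
        mismatches = []
        for n in (2, 4, 8):
            t = simulate_to_steady_cycle(p3_symmetric, settings_rr50,
                                         SimConfig(max_cycles=n, steady_tol=1e-30))
            mismatches.append(abs(t.V1[-1] - t.V1[0]) / np.max(np.abs(t.V1)))
        assert mismatches[0] >= mismatches[1] >= mismatches[2]

    @pytest.mark.parametrize("index", [2.0, 5.0, 10.0])
    def test_auto_peep_nonnegative_and_larger_in_slow_lung(self, cfg, index):
        p = make_patient(1.14, 5.3, index, 131.0, 88.0)
        s = VentSettings(RR=55, PIP=25, PEEP=5, IE=(1, 2))
        m = breath_metrics(simulate_to_steady_cycle(p, s, cfg), s)
        assert m.autoPEEP_1 >= -1e-9
        assert m.autoPEEP_2 >= -1e-9
        assert m.autoPEEP_1 >= m.autoPEEP_2

    def test_inertance_negligible_below_60_bpm(self, p3_symmetric):
        """Adding a small central inertance (0.1 cmH2O*s^2/l) at the fastest
        protocol rate changes Vt, MAP and WOB by < 2%."""
        s = VentSettings(RR=55, PIP=25, PEEP=5, IE=(1, 2))
        with_l = PatientParams(Rc=p3_symmetric.Rc, R1=p3_symmetric.R1,
                               R2=p3_symmetric.R2, C1=p3_symmetric.C1,
                               C2=p3_symmetric.C2, Cw=p3_symmetric.Cw, L=0.1)
        m0 = breath_metrics(simulate_to_steady_cycle(p3_symmetric, s, SimConfig()), s)
        m1 = breath_metrics(
            simulate_to_steady_cycle(with_l, s, SimConfig(use_inertance=True)), s)
        assert m1.Vt == pytest.approx(m0.Vt, rel=0.02)
        assert m1.MAP == pytest.approx(m0.MAP, rel=0.02)
        assert m1.WOB_vt == pytest.approx(m0.WOB_vt, rel=0.02)
        assert m1.PIP_meas == pytest.approx(m0.PIP_meas, rel=0.02)
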