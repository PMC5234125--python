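"""Cross-bridge dynamics, tension, ATP rate, and the Ca-drive machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardioem.myofilament import (
    MyoParams, MyoState, CaTransientTemplate, TensionTrace, sovf_thick,
    step_myofilament, active_tension, atp_rate, shifted_ca_drive,
    integrate_atp, run_twitch, run_twitch_reference, _myo_rhs,
)


class TestStepMyofilament:
    def test_no_calcium_no_activation(self):
        s = MyoState()
        for _ in range(10000):  # 1 s at dt = 0.1 ms
            s = step_myofilament(s, Ca_i=0.0, dt=0.1)
        assert s.XB_PreR + s.XB_PostR < 1e-3

    def test_pool_conserved_over_1e5_random_calcium_steps(self):
        rng = np.random.default_rng(7)
        y = MyoState().vector()
        dy = np.empty(6)
        mc = MyoParams().constants()
        from cardioem.myofilament import _myo_step
        for _ in range(100_000):
            _myo_step(y, rng.uniform(0.0, 0.003), 0.1, mc, dy)
        assert abs(y[:4].sum() - 1.0) < 1e-8

    def test_saturating_calcium_steady_state_matches_linear_solve(self):
        # oracle: at clamped Ca the 6-state system is linear; its steady
        # state solves A y = b independently of the time stepper
        ca = 0.005  # mM, saturating
        mc = MyoParams().constants()
        s = MyoState()
        for _ in range(60000):
            s = step_myofilament(s, Ca_i=ca, dt=0.1)
        # steady troponin occupancies
        tl = mc[0] * ca / (mc[0] * ca + mc[1])
        permtot = np.sqrt(1.0 / (1.0 + (mc[3] / tl) ** mc[4]))
        knp = mc[5] * permtot
        kpn = mc[6] * min(1.0 / permtot, mc[7])
        f, g, hf, hb, gxb = mc[8], mc[9], mc[10], mc[11], mc[12]
        A = np.array([
            [-knp, kpn, 0.0, 0.0],
            [knp, -(kpn + f), g, gxb],
            [0.0, f, -(g + hf), hb],
            [1.0, 1.0, 1.0, 1.0],
        ])
        b = np.array([0.0, 0.0, 0.0, 1.0])
        ref = np.linalg.solve(A, b)
        assert np.allclose(s.vector()[:4], ref, atol=1e-6)

    def test_sl_outside_range_rejected(self):
        with pytest.raises(ValueError, match="SL"):
            step_myofilament(MyoState(), Ca_i=0.001, SL=3.0)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            step_myofilament(MyoState(), Ca_i=-1.0)


class TestActiveTension:
    def test_zero_without_attached_bridges(self):
        assert active_tension(MyoState()) == 0.0

    def test_monotone_in_post_rotation_fraction(self):
        vals = [active_tension(MyoState(XB_PostR=x)) for x in
                (0.1, 0.2, 0.4)]
        assert vals[0] < vals[1] < vals[2]

    def test_tension_peak_lags_calcium_peak(self, ca_template_epi):
        tr = run_twitch(ca_template_epi, n_cycles=2)
        last = slice(-600, None)
        t_ca = float(ca_template_epi.t[np.argmax(ca_template_epi.ca)])
        t_tension = float(tr.t[last][np.argmax(tr.tension[last])]) % 600.0
        assert t_tension > t_ca


class TestAtpRate:
    def test_zero_overlap_means_zero_rate(self):
        # len_thin >= SL puts the thick filament fully outside single overlap
        p = MyoParams(overrides={"len_thin": 1.8})
        s = MyoState(XB_PostR=1.0, SL=1.9)
        assert sovf_thick(1.9, p) == 0.0
        assert atp_rate(s, p) == 0.0

    def test_product_form_with_full_attachment(self):
        # rate = g_xbT * SOVF with the attached fraction at unity
        p = MyoParams()
        sl = 1.5875  # SOVF_Thick = 2(SL - len_thin)/(len_thick - len_hbare) = 0.5
        assert sovf_thick(sl, p) == pytest.approx(0.5, abs=1e-12)
        s = MyoState(XB_PostR=1.0, SL=sl)
        assert atp_rate(s, p) == pytest.approx(0.5 * p.g_xbT, rel=1e-12)

    def test_cycle_integral_matches_adaptive_reference(self, ca_template_epi):
        tr = run_twitch(ca_template_epi, n_cycles=2)
        ref = run_twitch_reference(ca_template_epi, n_cycles=2)
        a = integrate_atp([tr], 600.0)
        b = integrate_atp([ref], 600.0)
        assert abs(a - b) / b < 0.01


class TestShiftedCaDrive:
    def test_zero_shift_is_identity(self, ca_template_epi):
        t = np.arange(0.0, 600.0)
        np.testing.assert_allclose(shifted_ca_drive(ca_template_epi, 0.0, t),
                                   ca_template_epi(t))

    def test_shift_moves_peak_by_eat(self, ca_template_epi):
        t = np.arange(0.0, 1200.0, 0.5)
        shifted = shifted_ca_drive(ca_template_epi, 40.0, t)
        t_pk0 = ca_template_epi.t[np.argmax(ca_template_epi.ca)]
        t_pk = t[np.argmax(shifted[t < 600.0])]
        assert t_pk == pytest.approx(t_pk0 + 40.0, abs=1.0)

    def test_diastolic_before_first_activation(self, ca_template_epi):
        v = shifted_ca_drive(ca_template_epi, 100.0, 50.0)
        assert v == ca_template_epi.diastolic

    def test_absent_eat_rejected(self, ca_template_epi):
        with pytest.raises(ValueError):
            shifted_ca_drive(ca_template_epi, np.nan, 10.0)

    def test_tension_peaks_separate_by_eat_difference(self, ca_template_epi):
        # oracle: direct integration of both shifted drives
        t1 = run_twitch(ca_template_epi, eat=20.0, n_cycles=1)
        t2 = run_twitch(ca_template_epi, eat=120.0, n_cycles=1)
        p1 = t1.t[np.argmax(t1.tension)]
        p2 = t2.t[np.argmax(t2.tension)]
        assert p2 - p1 == pytest.approx(100.0, abs=2.0)


class TestIntegrateAtp:
    def test_constant_rate_sums_over_nodes(self):
        t = np.arange(0.0, 601.0)
        traces = [TensionTrace(t=t, tension=np.zeros_like(t),
                               atp=np.full_like(t, 2.5)) for _ in range(8)]
        assert integrate_atp(traces, 600.0) == pytest.approx(8 * 2.5)

    def test_zero_traces_zero_total(self):
        t = np.arange(0.0, 601.0)
        traces = [TensionTrace(t=t, tension=np.zeros_like(t),
                               atp=np.zeros_like(t))]
        assert integrate_atp(traces, 600.0) == 0.0

    def test_short_trace_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            integrate_atp([TensionTrace(t=t, tension=np.zeros_like(t),
                                        atp=np.zeros_like(t))], 600.0)

    def test_sampling_refinement_changes_little(self, ca_template_epi):
        coarse = run_twitch(ca_template_epi, n_cycles=1, sample_dt=1.0)
        fine = run_twitch(ca_template_epi, n_cycles=1, sample_dt=0.25)
        a = integrate_atp([coarse], 590.0)
        b = integrate_atp([fine], 590.0)
        assert abs(a - b) / b < 1e-3


class TestProperties:
    @given(st.floats(1.4, 2.4))
    @settings(deadline=None, max_examples=60)
    def test_overlap_fraction_in_unit_interval(self, sl):
        v = sovf_thick(sl)
        assert 0.0 <= v <= 1.0

    @given(st.lists(st.floats(0.0, 0.005), min_size=5, max_size=5))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_tension_and_atp_nonnegative_on_any_drive(self, cas):
        s = MyoState()
        for ca in cas:
            for _ in range(100):
                s = step_myofilament(s, Ca_i=ca, dt=0.1)
            assert active_tension(s) >= 0.0
            assert atp_rate(s) >= 0.0

    def test_dispersion_never_raises_peak_of_summed_tension(self,
                                                            ca_template_epi):
        # 3-node toy ensembles with equal mean activation time
        def peak(eats):
            total = None
            for e in eats:
                tr = run_twitch(ca_template_epi, eat=e, n_cycles=2)
                total = tr.tension if total is None else total + tr.tension
            return total[-600:].max()
        uniform = peak([60.0, 60.0, 60.0])
        dispersed = peak([20.0, 60.0, 100.0])
        assert uniform >= dispersed
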