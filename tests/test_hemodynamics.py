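"""Ventricle surrogate, Windkessel loop, valves, and the failing preset."""

import warnings

import numpy as np
import pytest

from cardioem.hemodynamics import (
    WindkesselCompartment, CirculationParams, VentricleSurrogate, HemoState,
    ventricle_pressure, step_circulation, apply_failing_condition,
    run_cardiac_cycles, steady_state_check, default_circulation,
    default_ventricles,
)
from cardioem.sweep import pv_metrics
from conftest import synthetic_hemo_trace


class TestVentriclePressure:
    def test_passive_null_at_rest_volume(self):
        lv, _ = default_ventricles()
        assert ventricle_pressure(lv, 0.0, lv.V_rest) == pytest.approx(0.0)

    def test_active_pressure_linear_in_gain(self):
        lv, _ = default_ventricles()
        import dataclasses
        lv2 = dataclasses.replace(lv, alpha=2 * lv.alpha)
        base = ventricle_pressure(lv, 0.0, 70.0)
        p1 = ventricle_pressure(lv, 0.5, 70.0) - base
        p2 = ventricle_pressure(lv2, 0.5, 70.0) - base
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_monotone_in_tension(self):
        lv, _ = default_ventricles()
        ps = [ventricle_pressure(lv, T, 80.0) for T in (0.0, 0.3, 0.6)]
        assert ps[0] < ps[1] < ps[2]

    def test_nonpositive_volume_rejected(self):
        lv, _ = default_ventricles()
        with pytest.raises(ValueError):
            ventricle_pressure(lv, 0.1, 0.0)


class TestStepCirculation:
    def test_equal_pressures_freeze_all_volumes(self):
        p = default_circulation()
        # set every compartment (and both ventricles) to the same pressure
        for c in p.compartments():
            c.V = c.V0 + 10.0 * c.C
        st = HemoState(V_lv=100.0, V_rv=100.0, params=p)
        out = step_circulation(st, p, P_lv=10.0, P_rv=10.0, dt=0.1)
        for a, b in zip(out.params.compartments(), p.compartments()):
            assert a.V == pytest.approx(b.V, abs=1e-12)
        assert out.V_lv == st.V_lv and out.V_rv == st.V_rv

    def test_arterial_discharge_matches_closed_form(self):
        # oracle: exp(-t/RC) decay into a near-fixed-pressure venous sink
        R, C = 100.0, 1.0
        p = CirculationParams(
            sa=WindkesselCompartment(R=1e9, C=C, V=150.0, V0=50.0),
            sv=WindkesselCompartment(R=R, C=1e9, V=1e9 * 5.0, V0=0.0),
            pa=WindkesselCompartment(R=1e9, C=1.0, V=10.0, V0=10.0),
            pv=WindkesselCompartment(R=1e9, C=1.0, V=10.0, V0=10.0))
        st = HemoState(V_lv=50.0, V_rv=50.0, params=p)
        dt, T = 0.05, 150.0
        for _ in range(int(T / dt)):
            # high ventricular pressures keep the inflow valves closed;
            # the outflow paths see ~1e9 resistance, so only sa -> sv flows
            st = step_circulation(st, st.params, P_lv=500.0, P_rv=500.0,
                                  dt=dt)
        p_sink = 5.0
        expected = p_sink + (100.0 - p_sink) * np.exp(-T / (R * C))
        assert st.params.sa.P == pytest.approx(expected, rel=0.005)

    def test_total_volume_conserved(self):
        p = default_circulation()
        st = HemoState(V_lv=120.0, V_rv=120.0, params=p)
        total0 = st.total_volume
        rng = np.random.default_rng(3)
        for _ in range(500):
            st = step_circulation(st, st.params,
                                  P_lv=float(rng.uniform(0, 120)),
                                  P_rv=float(rng.uniform(0, 40)), dt=0.1)
        assert st.total_volume == pytest.approx(total0, rel=1e-12)

    def test_valve_flows_never_negative(self):
        p = default_circulation()
        st = HemoState(V_lv=100.0, V_rv=100.0, params=p)
        out = step_circulation(st, p, P_lv=0.0, P_rv=0.0, dt=0.1)
        # with zero ventricular pressure the outflow valves stay shut
        assert not out.valves["aortic"] and not out.valves["pulmonic"]
        assert out.V_lv >= st.V_lv  # only inflow possible


class TestFailingCondition:
    def test_compliances_scaled_by_0_9(self):
        p = default_circulation()
        f = apply_failing_condition(p)
        for a, b in zip(f.compartments(), p.compartments()):
            assert a.C == pytest.approx(0.9 * b.C, rel=1e-12)
            assert a.R == b.R

    def test_reapplication_guarded(self):
        f = apply_failing_condition(default_circulation())
        with pytest.raises(ValueError, match="already"):
            apply_failing_condition(f)


@pytest.fixture(scope="module")
def small_map(shell):
    from cardioem.tissue import EATMap
    rng = np.random.default_rng(11)
    eat = 20.0 + rng.uniform(0.0, 40.0, shell.n_nodes)
    return EATMap(eat=eat, cycle_onset=0.0, threshold=0.0, geom=shell)


class TestRunCardiacCycles:

    def test_conservation_and_convergence(self, small_map):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = run_cardiac_cycles(small_map, n_cycles=32)
        v0, v1 = h.total_volume
        assert abs(v1 - v0) / v0 < 1e-6
        assert steady_state_check(h)["converged"]

    def test_deterministic_repeat(self, small_map):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_cardiac_cycles(small_map, n_cycles=4)
            b = run_cardiac_cycles(small_map, n_cycles=4)
        assert np.array_equal(a.V_lv, b.V_lv)
        assert np.array_equal(a.atp_last, b.atp_last)

    def test_uniform_map_beats_dispersed_peak_pressure(self, shell):
        # oracle: direct pairwise simulation (synchronous contraction
        # generates at least the peak pressure of the dispersed one)
        from cardioem.tissue import EATMap
        n = shell.n_nodes
        uniform = EATMap(eat=np.full(n, 60.0), cycle_onset=0.0,
                         threshold=0.0, geom=shell)
        rng = np.random.default_rng(5)
        disp = EATMap(eat=60.0 + rng.uniform(-40, 40, n), cycle_onset=0.0,
                      threshold=0.0, geom=shell)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hu = run_cardiac_cycles(uniform, n_cycles=8)
            hd = run_cardiac_cycles(disp, n_cycles=8)
        assert hu.final_cycle()["P_lv"].max() >= hd.final_cycle()["P_lv"].max()

    def test_lv_volume_stays_above_floor(self, small_map):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = run_cardiac_cycles(small_map, n_cycles=6)
        assert h.V_lv.min() >= 5.0 - 1e-9


class TestSteadyStateCheck:
    def test_periodic_trace_converged(self):
        cyc = 70.0 + 15.0 * np.sin(2 * np.pi * np.arange(600) / 600.0)
        V = np.tile(cyc, 3)
        tr = synthetic_hemo_trace(V, np.zeros_like(V), cycle_length=600.0,
                                  n_cycles=3)
        out = steady_state_check(tr)
        assert out["converged"] and out["drift"] == pytest.approx(0.0, abs=1e-9)

    def test_growing_edv_not_converged(self):
        t = np.linspace(0, 6 * np.pi, 1800)
        V = 70.0 + 15.0 * np.sin(t) + np.linspace(0, 30, 1800)
        tr = synthetic_hemo_trace(V, np.zeros_like(V), cycle_length=600.0,
                                  n_cycles=3)
        assert not steady_state_check(tr)["converged"]

    def test_needs_three_cycles(self):
        V = np.full(600, 70.0)
        tr = synthetic_hemo_trace(V, V, cycle_length=300.0, n_cycles=2)
        with pytest.raises(ValueError):
            steady_state_check(tr)


class TestStrokeWorkQuadrature:
    def test_rectangle_loop_area(self):
        # V goes 50 -> 80 at P = 0 and back at P = 100: area 3000 mmHg mL
        V = np.concatenate([np.linspace(50, 80, 100),
                            np.full(50, 80.0),
                            np.linspace(80, 50, 100),
                            np.full(50, 50.0)])
        P = np.concatenate([np.zeros(100), np.linspace(0, 100, 50),
                            np.full(100, 100.0), np.linspace(100, 0, 50)])
        tr = synthetic_hemo_trace(V, P)
        m = pv_metrics(tr)
        assert m.SW == pytest.approx(3000.0, rel=0.005)

    def test_refined_sampling_agrees_within_half_percent(self):
        th = np.linspace(0, 2 * np.pi, 721)[:-1]
        V = 70 + 20 * np.cos(th)
        P = 60 + 50 * np.sin(th)
        area_exact = np.pi * 20 * 50
        m = pv_metrics(synthetic_hemo_trace(V, P))
        assert m.SW == pytest.approx(area_exact, rel=0.005)
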