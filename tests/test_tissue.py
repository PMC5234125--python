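"""Monodomain conduction: diffusion operator, activation maps, CV."""

import numpy as np
import pytest

from cardioem.tissue import (
    TissueParams, TissueGeometry, FieldState, EATMap, TissueRun,
    diffusion_coefficients, step_tissue, activation_map, eat_duration,
    measure_cv, cable_cv, calibrate_resistivity, run_tissue_paced,
)
from cardioem.fixtures import FixtureSpec, make_geometry


class TestDiffusionCoefficients:
    def test_reference_value_by_hand_arithmetic(self):
        # 1/(rho S Cm) with Ohm*F = s: 1e3/(162*2000*2) cm^2/ms
        D = diffusion_coefficients(TissueParams(
            rho=(162.0,) * 3, S=(2000.0,) * 3, Cm=2.0))
        assert D[0] == pytest.approx(1.543e-3, rel=1e-3)

    def test_doubling_resistivity_halves_diffusivity(self):
        d1 = diffusion_coefficients(TissueParams(rho=(162.0,) * 3))[0]
        d2 = diffusion_coefficients(TissueParams(rho=(324.0,) * 3))[0]
        assert d2 == pytest.approx(d1 / 2.0, rel=1e-12)

    def test_anisotropy_ratio(self):
        D = diffusion_coefficients(TissueParams(rho=(100.0, 400.0, 100.0)))
        assert D[0] / D[1] == pytest.approx(4.0, rel=1e-12)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            TissueParams(rho=(0.0, 162.0, 162.0))


class TestDiffusionOperator:
    def test_uniform_field_has_zero_laplacian(self, cable):
        fld = FieldState.resting(cable)
        out = step_tissue(fld, cable, TissueParams(), ionic=False)
        assert np.allclose(out.Y[:, 0], fld.Y[:, 0], atol=1e-12)

    def test_conservative_stencil_preserves_total_potential(self, cable):
        fld = FieldState.resting(cable)
        fld.Y[cable.n_nodes // 2, 0] += 10.0
        before = fld.Y[:, 0].sum()
        out = fld
        for _ in range(20):
            out = step_tissue(out, cable, TissueParams(), ionic=False)
        after = out.Y[:, 0].sum()
        assert abs(after - before) / abs(before) < 1e-10

    def test_elevated_node_spreads_to_neighbors(self, cable):
        fld = FieldState.resting(cable)
        mid = cable.n_nodes // 2
        fld.Y[mid, 0] += 10.0
        out = step_tissue(fld, cable, TissueParams(), ionic=False)
        assert out.Y[mid - 1, 0] > fld.Y[mid - 1, 0]
        assert out.Y[mid + 1, 0] > fld.Y[mid + 1, 0]
        assert out.Y[mid, 0] < fld.Y[mid, 0]

    def test_cfl_violation_rejected(self, cable):
        with pytest.raises(ValueError, match="stability"):
            step_tissue(FieldState.resting(cable), cable,
                        TissueParams(rho=(20.0,) * 3), dt=0.05)


def _synthetic_run(geom, t, V):
    return TissueRun(t=t, V=V, geom=geom, cycle_length=float(t[-1]))


class TestActivationMap:
    def test_single_crossing_time_interpolated(self, cable):
        t = np.arange(0.0, 100.0, 0.5)
        V = np.full((len(t), cable.n_nodes), -85.0, dtype=np.float32)
        V[t >= 37.0, 0] = 20.0
        emap = activation_map(_synthetic_run(cable, t, V), 0.0, 0.0)
        assert emap.eat[0] == pytest.approx(37.0, abs=0.5)

    def test_node_never_crossing_is_absent(self, cable):
        t = np.arange(0.0, 100.0, 0.5)
        V = np.full((len(t), cable.n_nodes), -85.0, dtype=np.float32)
        V[t >= 10.0, 0] = 20.0
        emap = activation_map(_synthetic_run(cable, t, V), 0.0, 0.0)
        assert np.isnan(emap.eat[1:]).all()
        assert emap.present.sum() == 1

    def test_planar_wave_gives_linear_activation_ramp(self, cable):
        # oracle: constructed wave at speed c -> EAT = x/c exactly
        c_cm_ms = 0.05  # 50 cm/s
        t = np.arange(0.0, 60.0, 0.25)
        x = cable.coords[:, 0]
        V = np.where(t[:, None] >= x[None, :] / c_cm_ms + 1.0, 20.0,
                     -85.0).astype(np.float32)
        emap = activation_map(_synthetic_run(cable, t, V), 0.0, 0.0)
        slope = np.polyfit(x[5:-5], emap.eat[5:-5], 1)[0]
        assert slope == pytest.approx(1.0 / c_cm_ms, rel=0.02)


class TestEatDuration:
    def test_duration_is_latest_activation(self, cable):
        eat = np.full(cable.n_nodes, np.nan)
        eat[:3] = [20.0, 60.0, 120.0]
        emap = EATMap(eat=eat, cycle_onset=0.0, threshold=0.0, geom=cable)
        assert eat_duration(emap) == 120.0
        eat[3] = 130.0
        assert eat_duration(emap) == 130.0

    def test_uniform_map(self, cable):
        emap = EATMap(eat=np.full(cable.n_nodes, 20.0), cycle_onset=0.0,
                      threshold=0.0)
        assert eat_duration(emap) == 20.0

    def test_empty_map_rejected(self, cable):
        emap = EATMap(eat=np.full(cable.n_nodes, np.nan), cycle_onset=0.0,
                      threshold=0.0)
        with pytest.raises(ValueError):
            eat_duration(emap)


class TestMeasureCv:
    def test_distance_over_time(self, cable):
        eat = np.full(cable.n_nodes, np.nan)
        a, b = 0, 56  # 56 * 0.025 cm = 1.4 cm apart
        eat[a], eat[b] = 10.0, 30.0
        emap = EATMap(eat=eat, cycle_onset=0.0, threshold=0.0, geom=cable)
        assert measure_cv(emap, a, b) == pytest.approx(70.0, rel=1e-9)

    def test_coincident_points_rejected(self, cable):
        eat = np.full(cable.n_nodes, np.nan)
        eat[0] = 10.0
        emap = EATMap(eat=eat, cycle_onset=0.0, threshold=0.0, geom=cable)
        with pytest.raises(ValueError):
            measure_cv(emap, 0, 0)

    def test_equal_activation_times_rejected(self, cable):
        eat = np.full(cable.n_nodes, np.nan)
        eat[0] = eat[10] = 10.0
        emap = EATMap(eat=eat, cycle_onset=0.0, threshold=0.0, geom=cable)
        with pytest.raises(ValueError):
            measure_cv(emap, 0, 10)


class TestCableCv:
    def test_reference_resistivity_gives_70_cm_s(self, cable, tissue_params):
        cv = cable_cv(cable, tissue_params.with_rho(162.0))
        assert cv == pytest.approx(70.0, rel=0.10)

    def test_cv_decreases_with_resistivity(self, cable, tissue_params):
        cv_lo = cable_cv(cable, tissue_params.with_rho(162.0))
        cv_hi = cable_cv(cable, tissue_params.with_rho(400.0))
        assert cv_hi < cv_lo


class TestCalibrateResistivity:
    def test_target_70_recovers_reference_resistivity(self, cable,
                                                      tissue_params):
        rho, achieved = calibrate_resistivity(70.0, cable, tissue_params)
        assert rho == pytest.approx(162.0, rel=0.15)
        assert achieved == pytest.approx(70.0, rel=0.01)

    def test_unreachable_target_rejected(self, cable, tissue_params):
        with pytest.raises((ValueError, RuntimeError)):
            calibrate_resistivity(500.0, cable, tissue_params)


class TestPacedTissue:
    def test_requires_stimulus_sites(self, cable, tissue_params):
        from types import SimpleNamespace
        proto = SimpleNamespace(site_nodes=[], site_onsets=[],
                                stim_nodes=(), stim_onsets=(),
                                cycle_length=600.0, amplitude=-52.0,
                                duration=1.0)
        with pytest.raises(ValueError, match="site"):
            run_tissue_paced(cable, tissue_params, proto, 100.0)

    def test_one_eat_map_per_complete_cycle(self, cable, tissue_params):
        from types import SimpleNamespace
        proto = SimpleNamespace(site_nodes=[0, 1], site_onsets=[20.0, 20.0],
                                stim_nodes=(), stim_onsets=(),
                                cycle_length=300.0, amplitude=-80.0,
                                duration=2.0)
        run = run_tissue_paced(cable, tissue_params, proto, 600.0)
        assert len(run.eat_maps) == 2
        assert run.final_eat is run.eat_maps[-1]

    def test_repeated_runs_bit_identical(self, cable, tissue_params):
        from types import SimpleNamespace
        proto = SimpleNamespace(site_nodes=[0, 1], site_onsets=[20.0, 20.0],
                                stim_nodes=(), stim_onsets=(),
                                cycle_length=300.0, amplitude=-80.0,
                                duration=2.0)
        a = run_tissue_paced(cable, tissue_params, proto, 300.0)
        b = run_tissue_paced(cable, tissue_params, proto, 300.0)
        assert np.array_equal(a.V, b.V)
        assert np.array_equal(a.final_eat.eat, b.final_eat.eat,
                              equal_nan=True)

    def test_stimulated_sites_clamped_to_onset(self, cable, tissue_params):
        from types import SimpleNamespace
        proto = SimpleNamespace(site_nodes=[0, 1], site_onsets=[20.0, 20.0],
                                stim_nodes=(), stim_onsets=(),
                                cycle_length=300.0, amplitude=-80.0,
                                duration=2.0)
        run = run_tissue_paced(cable, tissue_params, proto, 300.0,
                               clamp_stim_sites=True)
        assert np.nanmin(run.final_eat.eat) == 20.0

    def test_tabulated_reaction_matches_exact_path(self, cable,
                                                   tissue_params):
        from types import SimpleNamespace
        proto = SimpleNamespace(site_nodes=[0, 1], site_onsets=[5.0, 5.0],
                                stim_nodes=(), stim_onsets=(),
                                cycle_length=200.0, amplitude=-80.0,
                                duration=2.0)
        a = run_tissue_paced(cable, tissue_params, proto, 60.0,
                             sample_dt=0.5, tabulated=False,
                             clamp_stim_sites=False)
        b = run_tissue_paced(cable, tissue_params, proto, 60.0,
                             sample_dt=0.5, tabulated=True,
                             clamp_stim_sites=False)
        assert np.abs(a.V - b.V).max() < 0.05  # mV, over a full upstroke

    def test_spatial_convergence_of_cv(self):
        # halving dx changes CV by < 3% in the convergent regime (the
        # working resolution dx = 0.025 carries the model family's known
        # coarse-grid CV bias, which is part of the 70 cm/s convention)
        cvs = {}
        for dx in (0.0125, 0.00625):
            geom = make_geometry(FixtureSpec(kind="cable", dimensions=(2.0,),
                                             dx=dx, layers=(0.0, 0.0, 1.0)))
            cvs[dx] = cable_cv(geom, TissueParams(dt=0.01))
        assert abs(cvs[0.0125] - cvs[0.00625]) / cvs[0.00625] < 0.03
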