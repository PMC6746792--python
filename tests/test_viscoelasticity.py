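"""Four-element creep compliance: model, fitting and recovery prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dorsaflow import (
    SyntheticScenario,
    Trajectory,
    compliance_from_displacement,
    convert_moduli,
    fit_kv4,
    gen_creep_tracks,
    kv4_compliance,
    kv4_relaxation_time,
    recovery_curve,
    terminal_drag_force,
)
from dorsaflow.errors import QCError, TrackDataError
from dorsaflow.viscoelasticity import CreepSeries, geometry_prefactor

CENTRAL = dict(g0=500.0, g1=200.0, mu0=550.0, mu1=50.0)

positive = st.floats(1.0, 1e5, allow_nan=False)


def _series_from_model(ctx, f_a=1e-9, dt=0.5, duration=30.0, **params):
    t = np.arange(0.0, duration + dt / 2, dt)
    j = np.zeros_like(t)
    j[1:] = kv4_compliance(t[1:], params["g0"], params["g1"], params["mu0"],
                           params["mu1"])
    disp = j * f_a / geometry_prefactor(ctx)
    return CreepSeries(times=t, displacement=disp, compliance=j,
                       applied_force=f_a, context=ctx)


class TestComplianceSeries:
    def _flat_track(self, x_um):
        t = np.arange(0.0, 40.0, 1.0)
        x = np.zeros_like(t)
        x[t > 5.0] = x_um
        return Trajectory(track_id=0, times=t, x=100.0 + x, y=np.full(t.size, 50.0))

    def test_zero_displacement_gives_zero_compliance(self, ctx):
        traj = self._flat_track(0.0)
        series = compliance_from_displacement(traj, 5.0, 35.0, 1e-9, ctx)
        np.testing.assert_allclose(series.compliance, 0.0)

    def test_pointwise_value(self, ctx):
        # X = 1 µm, a = 1.4 µm, C = 1.1848, F = 1 nN → J = 6πaXC/F ≈ 3.125e-2
        traj = self._flat_track(1.0)
        series = compliance_from_displacement(traj, 5.0, 35.0, 1e-9, ctx)
        assert series.compliance[-1] == pytest.approx(3.125e-2, rel=1e-3)

    def test_compliance_inverse_in_force(self, ctx):
        traj = self._flat_track(1.0)
        j1 = compliance_from_displacement(traj, 5.0, 35.0, 1e-9, ctx).compliance
        j2 = compliance_from_displacement(traj, 5.0, 35.0, 2e-9, ctx).compliance
        np.testing.assert_allclose(j2, j1 / 2.0)

    def test_window_outside_track_raises(self, ctx):
        traj = self._flat_track(1.0)
        with pytest.raises(ValueError):
            compliance_from_displacement(traj, 5.0, 100.0, 1e-9, ctx)


class TestKV4Model:
    @settings(deadline=None, max_examples=50)
    @given(g0=positive, g1=positive, mu0=positive, mu1=positive)
    def test_instantaneous_compliance(self, g0, g1, mu0, mu1):
        assert kv4_compliance(0.0, g0, g1, mu0, mu1) == pytest.approx(
            1.0 / (g0 + g1), rel=1e-9
        )

    def test_hand_evaluated_relaxation_time(self):
        assert kv4_relaxation_time(500.0, 200.0, 50.0) == pytest.approx(0.35)
        assert kv4_compliance(0.0, **CENTRAL) == pytest.approx(1.4286e-3, rel=1e-4)

    def test_terminal_slope_is_flow_viscosity(self):
        t = np.array([1e4, 1e4 + 1.0])
        j = kv4_compliance(t, **CENTRAL)
        assert (j[1] - j[0]) == pytest.approx(1.0 / CENTRAL["mu0"], rel=1e-9)

    def test_non_decreasing(self):
        t = np.linspace(0.0, 100.0, 2000)
        j = kv4_compliance(t, **CENTRAL)
        assert np.all(np.diff(j) > 0)

    def test_rejects_non_positive_parameters(self):
        with pytest.raises(ValueError):
            kv4_compliance(1.0, -1.0, 200.0, 550.0, 50.0)


class TestModulusConversion:
    def test_reference_conversion(self):
        assert convert_moduli(500.0, 0.4) == pytest.approx(1400.0)

    def test_incompressible_identity(self):
        assert convert_moduli(500.0, 0.5) == pytest.approx(3 * 500.0)

    def test_linearity(self):
        assert convert_moduli(700.0, 0.4) == pytest.approx(
            convert_moduli(500.0, 0.4) + convert_moduli(200.0, 0.4)
        )

    def test_domain(self):
        with pytest.raises(ValueError):
            convert_moduli(500.0, 0.6)


class TestCreepFit:
    def test_noiseless_recovery_within_1_percent(self, ctx):
        series = _series_from_model(ctx, **CENTRAL)
        fit = fit_kv4(series)
        assert fit.g0 == pytest.approx(CENTRAL["g0"], rel=0.01)
        assert fit.g1 == pytest.approx(CENTRAL["g1"], rel=0.01)
        assert fit.mu0_shear == pytest.approx(CENTRAL["mu0"], rel=0.01)
        assert fit.mu1_shear == pytest.approx(CENTRAL["mu1"], rel=0.01)
        assert fit.tau == pytest.approx(0.35, rel=0.01)

    def test_scale_equivariance(self, ctx):
        # multiplying F_A and X(t) by the same factor leaves the fit unchanged
        a = _series_from_model(ctx, f_a=1e-9, **CENTRAL)
        b = CreepSeries(
            times=a.times,
            displacement=a.displacement * 7.0,
            compliance=a.compliance,
            applied_force=a.applied_force * 7.0,
            context=ctx,
        )
        fa, fb = fit_kv4(a), fit_kv4(b)
        assert fb.g0 == pytest.approx(fa.g0, rel=1e-6)
        assert fb.e0_plus_e1 == pytest.approx(fa.e0_plus_e1, rel=1e-6)

    def test_converted_moduli_consistent(self, ctx):
        fit = fit_kv4(_series_from_model(ctx, **CENTRAL))
        assert fit.e0 == pytest.approx(2.8 * fit.g0, rel=1e-9)
        assert fit.e0_plus_e1 == pytest.approx(fit.e0 + fit.e1, rel=1e-9)

    def test_tied_mode_runs(self, ctx):
        series = _series_from_model(
            ctx, g0=500.0, g1=200.0, mu0=50.0, mu1=50.0
        )
        fit = fit_kv4(series, tied=True)
        assert fit.mu0_shear == fit.mu1_shear
        assert fit.g0 == pytest.approx(500.0, rel=0.02)

    def test_too_short_series_is_qc_error(self, ctx):
        series = _series_from_model(ctx, duration=5.0, **CENTRAL)
        short = CreepSeries(
            times=series.times[:10],
            displacement=series.displacement[:10],
            compliance=series.compliance[:10],
            applied_force=series.applied_force,
            context=ctx,
        )
        with pytest.raises(QCError):
            fit_kv4(short)

    def test_negative_terminal_slope_is_data_error(self, ctx):
        series = _series_from_model(ctx, **CENTRAL)
        flipped = CreepSeries(
            times=series.times,
            displacement=-series.displacement,
            compliance=-series.compliance,
            applied_force=series.applied_force,
            context=ctx,
        )
        with pytest.raises(TrackDataError):
            fit_kv4(flipped)

    def test_generator_single_cell_recovery(self, ctx):
        scenario = SyntheticScenario(
            mode="creep", n_particles=1, noise_sigma=0.0, param_sigma_log=0.0
        )
        table, truth = gen_creep_tracks(scenario, ctx)
        f_a = float(truth["F_A_N"].iloc[0])
        series = compliance_from_displacement(
            table.trajectories[0], 10.0, 100.0, f_a, ctx
        )
        fit = fit_kv4(series)
        assert fit.g0 == pytest.approx(500.0, rel=0.01)
        assert fit.g1 == pytest.approx(200.0, rel=0.01)
        assert fit.mu0_shear == pytest.approx(550.0, rel=0.01)
        assert fit.mu1_shear == pytest.approx(50.0, rel=0.01)


class TestRecoveryPrediction:
    def test_continuity_with_creep_endpoint(self, ctx):
        f_a = 1e-9
        fit = fit_kv4(_series_from_model(ctx, f_a=f_a, **CENTRAL))
        pref = f_a / geometry_prefactor(ctx)
        x0 = recovery_curve(0.0, fit, 30.0, f_a, ctx)
        # creep endpoint minus the instantaneous elastic recoil
        expected = pref * (
            kv4_compliance(30.0, **CENTRAL) - 1.0 / (CENTRAL["g0"] + CENTRAL["g1"])
        )
        assert x0 == pytest.approx(expected, rel=1e-3)

    def test_purely_elastic_limit_recovers_fully(self, ctx):
        # as the flow viscosity grows the residual displacement vanishes
        fit = fit_kv4(
            _series_from_model(ctx, g0=500.0, g1=200.0, mu0=1e7, mu1=50.0)
        )
        start = recovery_curve(0.0, fit, 30.0, 1e-9, ctx)
        far = recovery_curve(1e4, fit, 30.0, 1e-9, ctx)
        assert abs(far) < 0.01 * start
        assert far == pytest.approx(1e-9 / geometry_prefactor(ctx) * 30.0 / 1e7,
                                    rel=0.05)

    def test_residual_displacement(self, ctx):
        f_a = 1e-9
        fit = fit_kv4(_series_from_model(ctx, f_a=f_a, duration=90.0, **CENTRAL))
        pref = f_a / geometry_prefactor(ctx)
        residual = pref * 90.0 / CENTRAL["mu0"]
        assert recovery_curve(10 * 0.35, fit, 90.0, f_a, ctx) == pytest.approx(
            residual, rel=0.01
        )
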