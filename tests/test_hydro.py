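"""Channel flow, wall-corrected drag, particle advection and the logistic calibration."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from dorsaflow import (
    ChannelGeometry,
    HydroContext,
    advect_particle,
    applied_force,
    build_calibration,
    channel_velocity,
    drag_force,
    ligands_per_particle,
    schiller_naumann_cd,
    terminal_drag_force,
    wall_correction_factor,
)
from dorsaflow.errors import ExtrapolationWarning
from dorsaflow.hydro_calibration import (
    DEFAULT_HEIGHTS,
    _logistic,
    channel_velocity_duct,
    fit_logistic,
)

GEOM = ChannelGeometry()


class TestChannelVelocity:
    def test_no_slip_at_walls(self):
        assert channel_velocity(0.0, 10.0, GEOM) == 0.0
        assert channel_velocity(GEOM.height, 10.0, GEOM) == 0.0

    def test_midplane_poiseuille(self):
        # u(H/2) = 1.5 Q/(wH); Q = 10 µl/min in a 1 mm x 100 µm channel
        u = channel_velocity(GEOM.height / 2, 10.0, GEOM)
        assert u == pytest.approx(2.50e-3, rel=1e-12)

    @pytest.mark.parametrize("q", [1.0, 10.0, 1000.0])
    def test_mass_conservation(self, q):
        flux, _ = quad(lambda z: channel_velocity(z, q, GEOM), 0, GEOM.height)
        assert flux * GEOM.width == pytest.approx(q * 1e-9 / 60.0, rel=1e-8)

    def test_out_of_channel_raises(self):
        with pytest.raises(ValueError):
            channel_velocity(-1e-6, 10.0, GEOM)
        with pytest.raises(ValueError):
            channel_velocity(GEOM.height / 2, -1.0, GEOM)

    def test_duct_profile_vs_plate_away_from_side_walls(self):
        # > 200 µm from the side walls the duct profile is flat in y (shape
        # identical to the plate profile) but uniformly higher by the
        # side-wall flux-deficit factor 1/(1 − 0.63 H/w) ≈ 1.067, because
        # the plate normalisation spreads the flux over the full width
        deficit = 1.0 / (1.0 - 0.63 * GEOM.height / GEOM.width)
        for y in (300e-6, 500e-6, 700e-6):
            for z in (5e-6, 25e-6, 50e-6):
                plate = channel_velocity(z, 200.0, GEOM)
                duct = channel_velocity_duct(y, z, 200.0, GEOM)
                assert duct / plate == pytest.approx(deficit, rel=0.01)


class TestWallCorrection:
    def test_reference_height_value(self):
        # 2.8 µm bead with centroid 5 µm above the wall
        assert wall_correction_factor(2.8e-6, 5e-6) == pytest.approx(1.1848, abs=5e-4)

    def test_free_stream_limit(self):
        assert wall_correction_factor(2.8e-6, 1.0) == pytest.approx(1.0, abs=1e-6)

    def test_closer_wall_value(self):
        assert wall_correction_factor(2.8e-6, 3e-6) == pytest.approx(1.3505, abs=5e-4)

    def test_monotone_increasing_towards_wall(self):
        heights = np.linspace(1.4e-6, 100e-6, 200)
        c = [wall_correction_factor(2.8e-6, h) for h in heights]
        assert np.all(np.diff(c) < 0)  # decreasing with h
        assert min(c) >= 1.0

    def test_contact_violation_raises(self):
        with pytest.raises(ValueError):
            wall_correction_factor(2.8e-6, 1e-6)


class TestSchillerNaumann:
    def test_unit_reynolds(self):
        assert schiller_naumann_cd(1.0) == pytest.approx(27.6)

    def test_stokes_limit(self):
        re = 1e-8
        assert schiller_naumann_cd(re) * re == pytest.approx(24.0, rel=1e-4)

    def test_intermediate_value(self):
        # direct evaluation: (24/0.133)(1 + 0.15·0.133^0.687)
        assert schiller_naumann_cd(0.133) == pytest.approx(187.22, rel=1e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            schiller_naumann_cd(0.0)


class TestAdvection:
    def test_zero_slip_is_fixed_point(self, ctx):
        vf = channel_velocity(5e-6, 10.0, ctx.geometry)
        state = advect_particle(5e-6, 10.0, ctx, v0=vf)
        assert state.n_steps == 0
        assert state.particle_velocity == vf

    def test_terminal_velocity_matches_local_fluid(self, ctx):
        state = advect_particle(5e-6, 10.0, ctx)
        assert state.fluid_velocity == pytest.approx(4.75e-4, rel=1e-9)
        assert state.particle_velocity == pytest.approx(4.75e-4, rel=1e-4)

    @pytest.mark.parametrize("z", [5e-6, 25e-6, 50e-6])
    def test_terminal_slip_below_tolerance(self, ctx, z):
        state = advect_particle(z, 1000.0, ctx)
        assert state.slip_ratio < 1e-4


class TestDragForce:
    def test_zero_speed(self, ctx):
        assert drag_force(0.0, ctx) == 0.0

    def test_hand_evaluated_value(self, ctx):
        # 6π·(1.4 µm)·(1e-3 Pa·s)·(4.75e-4 m/s)·1.1848 ≈ 1.485e-11 N
        f = drag_force(4.75e-4, ctx)
        assert f == pytest.approx(1.485e-11, rel=2e-3)

    def test_linearity_at_low_reynolds(self, ctx):
        u = 1e-6
        assert drag_force(2 * u, ctx) == pytest.approx(2 * drag_force(u, ctx))

    def test_linear_in_flow_rate_in_stokes_regime(self, ctx):
        # Re_p < 1e-3 for Q <= 5 µl/min at z = 5 µm: pure Stokes branch
        f1 = terminal_drag_force(5e-6, 0.5, ctx)
        f10 = terminal_drag_force(5e-6, 5.0, ctx)
        assert f10 / f1 == pytest.approx(10.0, rel=1e-3)

    def test_increasing_in_flow_rate(self, ctx):
        forces = [terminal_drag_force(5e-6, q, ctx) for q in (10, 100, 500, 1400)]
        assert np.all(np.diff(forces) > 0)


class TestCalibration:
    def test_logistic_self_consistency(self):
        # samples generated from a known logistic are recovered within 1 %
        true = (10e-12, 1500e-12, 20e-6, 2.0)
        f = _logistic(DEFAULT_HEIGHTS, *true)
        (a1, a2, x0, p), r2, _ = fit_logistic(DEFAULT_HEIGHTS, f)
        for got, want in zip((a1, a2, x0, p), true):
            assert got == pytest.approx(want, rel=0.01)
        assert r2 > 0.999

    @pytest.mark.parametrize("q", [10.0, 200.0, 1000.0])
    def test_fit_quality_on_default_grid(self, ctx, q):
        cal = build_calibration(q, ctx)
        assert cal.r_squared > 0.95

    def test_fitted_force_monotone_in_height(self, ctx):
        cal = build_calibration(200.0, ctx)
        x = np.linspace(1e-6, ctx.geometry.height / 2, 100)
        assert np.all(np.diff(cal.evaluate(x)) > 0)

    def test_applied_force_reproduces_samples(self, ctx):
        cal = build_calibration(200.0, ctx)
        for h, f in zip(cal.heights, cal.forces):
            assert applied_force(h, cal) == pytest.approx(f, rel=0.15)

    def test_low_flow_force_scale(self, ctx):
        # ≈ 14 pN maximal bead drag at 10 µl/min, 5 µm reference height
        cal = build_calibration(10.0, ctx)
        assert applied_force(5e-6, cal) == pytest.approx(14e-12, rel=0.10)

    def test_high_flow_force_scale(self, ctx):
        cal = build_calibration(1000.0, ctx)
        assert applied_force(5e-6, cal) == pytest.approx(1.56e-9, rel=0.10)

    def test_extrapolation_warns(self, ctx):
        cal = build_calibration(200.0, ctx)
        with pytest.warns(ExtrapolationWarning):
            applied_force(90e-6, cal)

    def test_round_trip_json(self, ctx, tmp_path):
        from dorsaflow import ForceCalibration

        cal = build_calibration(200.0, ctx)
        path = tmp_path / "cal.json"
        cal.save(path)
        back = ForceCalibration.load(path)
        assert back.evaluate(5e-6) == pytest.approx(cal.evaluate(5e-6))


class TestLigandAccounting:
    def test_molecules_per_mg(self):
        molecules, _ = ligands_per_particle(8.0, 150.0, 6.09e8)
        assert molecules == pytest.approx(3.2e16, rel=0.01)

    def test_per_particle_rounded(self):
        _, per = ligands_per_particle(8.0, 150.0, 6.09e8)
        assert per == 5e7

    def test_inverse_proportional_to_weight(self):
        m1, _ = ligands_per_particle(8.0, 150.0, 6.09e8)
        m2, _ = ligands_per_particle(8.0, 300.0, 6.09e8)
        assert m2 == pytest.approx(m1 / 2)


def test_context_rejects_contact_violation():
    with pytest.raises(ValueError):
        HydroContext(reference_height=1e-6)


def test_full_force_spectrum_span(ctx):
    # ~14 pN at 10 µl/min up to ~2 nN at 1400 µl/min at the reference height
    lo = terminal_drag_force(5e-6, 10.0, ctx)
    hi = terminal_drag_force(5e-6, 1400.0, ctx)
    assert lo == pytest.approx(14e-12, rel=0.10)
    assert hi == pytest.approx(2e-9, rel=0.10)


def test_advection_example_speed():
    state = advect_particle(5e-6, 10.0, HydroContext())
    assert state.particle_velocity == pytest.approx(4.75e-4, rel=1e-3)


def test_logistic_example_math():
    assert math.isclose(
        _logistic(20e-6, 10e-12, 1500e-12, 20e-6, 2.0), (10e-12 + 1500e-12) / 2
    )
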