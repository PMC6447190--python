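"""Perspective projection and retinal kinematics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stereospeed import (
    ARCMIN_PER_RAD,
    SpeedChangeInterval,
    ViewingGeometry,
    angle_to_screen,
    angular_speed,
    build_retina_interval,
    build_world_interval,
    derive_retina_speed,
    recover_geometry,
    render_stereo,
    trace_retinal,
    world_to_angle,
    world_to_screen,
)


class TestProjection:
    @pytest.mark.parametrize(
        "x, z, expected",
        [
            (0.0, 100.0, 0.0),
            (3.0, 117.0, math.atan(3.0 / 117.0)),  # 0.025635 rad
            (-3.0, 117.0, -math.atan(3.0 / 117.0)),
        ],
    )
    def test_world_to_angle_examples(self, x, z, expected):
        assert world_to_angle(x, z) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "angle, d, expected",
        [(0.0, 97.0, 0.0), (math.atan(3.0 / 117.0), 97.0, 97.0 * math.tan(math.atan(3.0 / 117.0)))],
    )
    def test_angle_to_screen_examples(self, angle, d, expected):
        assert angle_to_screen(angle, d) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "x, z, d, expected",
        [
            (3.0, 97.0, 97.0, 3.0),  # screen-plane point projects to itself
            (3.0, 117.0, 97.0, 97.0 * 3.0 / 117.0),  # 2.4872 cm
            (3.0, 77.0, 97.0, 97.0 * 3.0 / 77.0),  # 3.7792 cm
        ],
    )
    def test_world_to_screen_examples(self, x, z, d, expected):
        assert world_to_screen(x, z, d) == pytest.approx(expected, rel=1e-9)
        assert float(expected) == pytest.approx(
            {(3.0, 117.0): 2.4872, (3.0, 77.0): 3.7792, (3.0, 97.0): 3.0}[(x, z)], abs=5e-5
        )

    @given(
        x=st.floats(-20, 20),
        z=st.floats(5, 500),
        d=st.floats(20, 200),
    )
    @settings(max_examples=200, deadline=None)
    def test_direct_projection_equals_composition(self, x, z, d):
        direct = world_to_screen(x, z, d)
        composed = angle_to_screen(world_to_angle(x, z), d)
        assert direct == pytest.approx(composed, rel=1e-12, abs=1e-12)

    @pytest.mark.parametrize("fn", [world_to_angle, lambda x, z: world_to_screen(x, z, 97.0),
                                    lambda x, z: angular_speed(x, z, 40.0)])
    def test_nonpositive_depth_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(3.0, 0.0)
        with pytest.raises(ValueError):
            fn(3.0, -5.0)

    def test_angle_at_quarter_turn_rejected(self):
        with pytest.raises(ValueError):
            angle_to_screen(math.pi / 2, 97.0)


class TestAngularSpeed:
    @pytest.mark.parametrize(
        "z, v, printed",
        [(117.0, 40.0, 30.1), (97.0, 40.0, 43.8), (77.0, 40.0, 69.5)],
    )
    def test_fast_standard_cells(self, z, v, printed):
        assert round(angular_speed(3.0, z, v), 1) == printed

    def test_stationary_object(self):
        assert angular_speed(3.0, 100.0, 0.0) == 0.0

    def test_speed_grows_as_object_nears(self):
        z = np.linspace(150, 20, 40)
        s = angular_speed(3.0, z, 40.0)
        assert np.all(np.diff(s) > 0)

    @given(
        x=st.floats(0.5, 10),
        z=st.floats(10, 300),
        v=st.floats(1, 100),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_numerical_derivative_of_angle(self, x, z, v):
        """Central difference of the visual angle is the independent oracle."""
        dt = 1e-6
        num = (world_to_angle(x, z - v * dt) - world_to_angle(x, z + v * dt)) / (2 * dt)
        assert angular_speed(x, z, v) == pytest.approx(num * ARCMIN_PER_RAD, rel=1e-6)


class TestWorldTrajectory:
    def test_fast_standard_placement(self, geom, fast_standard):
        traj = build_world_interval(fast_standard, geom)
        assert traj.z0 == pytest.approx(117.0)
        assert traj.z1 == pytest.approx(77.0)

    def test_fast_max_change_depths(self, geom, fast_max):
        traj = build_world_interval(fast_max, geom)
        assert traj.z0 == pytest.approx(117.0)
        assert traj.z_of_t(0.5) == pytest.approx(112.0)
        assert traj.z1 == pytest.approx(77.0)

    def test_slow_standard_placement(self, geom, slow_standard):
        traj = build_world_interval(slow_standard, geom)
        assert (traj.z0, traj.z1) == (pytest.approx(107.0), pytest.approx(87.0))

    def test_object_passing_eye_rejected(self, geom):
        with pytest.raises(ValueError, match="pass the eye"):
            build_world_interval(SpeedChangeInterval(200.0, 200.0), geom)

    def test_depth_strictly_decreasing_and_continuous(self, geom, fast_max):
        traj = build_world_interval(fast_max, geom)
        t = np.linspace(0, 1, 1001)
        z = traj.z_of_t(t)
        assert np.all(np.diff(z) < 0)
        assert np.all(z > 0)

    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            SpeedChangeInterval(40.0, 40.0, change_time_s=1.5, duration_s=1.0)
        with pytest.raises(ValueError):
            SpeedChangeInterval(40.0, 40.0, duration_s=0.0)


class TestRetinalTrace:
    TABLE_CELLS = [
        # (v_before, v_after, symbol, printed, tol)
        (40.0, 40.0, "a", 30.1, 0.1),
        (40.0, 40.0, "b", 43.8, 0.1),
        (40.0, 40.0, "d", 69.5, 0.1),
        (10.0, 70.0, "a", 7.5, 0.1),
        (10.0, 70.0, "b", 8.2, 0.1),
        (10.0, 70.0, "c", 57.6, 0.3),
        (10.0, 70.0, "d", 121.4, 0.3),
        (20.0, 20.0, "a", 18.0, 0.1),
        (20.0, 20.0, "b", 21.9, 0.1),
        (20.0, 20.0, "d", 27.2, 0.1),
        (5.0, 35.0, "a", 4.5, 0.1),
        (5.0, 35.0, "b", 4.7, 0.1),
        (5.0, 35.0, "c", 33.1, 0.3),
        (5.0, 35.0, "d", 47.6, 0.1),
    ]

    @pytest.mark.parametrize("vb, va, symbol, printed, tol", TABLE_CELLS)
    def test_speed_table_reproduction(self, geom, vb, va, symbol, printed, tol):
        trace = trace_retinal(build_world_interval(SpeedChangeInterval(vb, va), geom), geom)
        assert round(getattr(trace, symbol), 1) == pytest.approx(printed, abs=tol)

    def test_constant_world_speed_accelerates_on_retina(self, geom, fast_standard):
        trace = trace_retinal(build_world_interval(fast_standard, geom), geom)
        cyc = trace.speed_arcmin_per_s[:, 1, 2]
        assert np.all(np.diff(cyc) > 0)

    def test_b_le_c_iff_speed_steps_up(self, geom):
        up = trace_retinal(build_world_interval(SpeedChangeInterval(10.0, 70.0), geom), geom)
        flat = trace_retinal(build_world_interval(SpeedChangeInterval(40.0, 40.0), geom), geom)
        assert up.b < up.c
        assert flat.b == pytest.approx(flat.c)

    def test_frame_sampling(self, geom, fast_standard):
        trace = trace_retinal(build_world_interval(fast_standard, geom), geom)
        assert trace.frame_times_s[0] == 0.0
        assert trace.frame_times_s[-1] == pytest.approx(1.0)
        assert len(trace.frame_times_s) == 86
        assert trace.angle_arcmin.shape == (86, 2, 3)

    def test_eye_channels_straddle_cyclopean(self, geom, fast_standard):
        """Right line: right eye (closer) sees a smaller angle than the left eye."""
        trace = trace_retinal(build_world_interval(fast_standard, geom), geom)
        right_line = trace.angle_arcmin[:, 1, :]
        assert np.all(right_line[:, 0] > right_line[:, 2])  # left eye channel
        assert np.all(right_line[:, 1] < right_line[:, 2])  # right eye channel


class TestRetinaInterval:
    def test_standard_is_constant(self, geom):
        trace = build_retina_interval(47.6, 47.6, geom=geom)
        cyc = trace.speed_arcmin_per_s[:, 1, 2]
        assert np.ptp(cyc) <= 1e-9
        assert (trace.a, trace.b, trace.c, trace.d) == (47.6, 47.6, 47.6, 47.6)

    def test_displacement_conserved_at_max_change(self, geom):
        standard = build_retina_interval(47.5, 47.5, geom=geom)
        changed = build_retina_interval(7.6, 87.4, geom=geom)
        def disp(tr):
            return tr.angle_arcmin[-1, 1, 2] - tr.angle_arcmin[0, 1, 2]
        assert disp(changed) == pytest.approx(disp(standard), abs=1e-9)

    def test_zero_change_level_identical_to_standard(self, geom):
        a = build_retina_interval(22.3, 22.3, geom=geom)
        b = build_retina_interval(22.3, 22.3, geom=geom)
        np.testing.assert_array_equal(a.angle_arcmin, b.angle_arcmin)

    def test_separation_grows_only_without_control(self, geom):
        retina = build_retina_interval(47.6, 47.6, geom=geom)
        control = build_retina_interval(47.6, 47.6, geom=geom, control=True)
        sep_r = retina.angle_arcmin[:, 1, 2] - retina.angle_arcmin[:, 0, 2]
        sep_c = control.angle_arcmin[:, 1, 2] - control.angle_arcmin[:, 0, 2]
        assert np.all(np.diff(sep_r) > 0)
        np.testing.assert_allclose(np.diff(sep_c), 0, atol=1e-12)
        # control translates: both lines move in the same direction
        assert np.all(np.diff(control.angle_arcmin[:, 0, 2]) > 0)


class TestDeriveRetinaSpeed:
    def test_fast_standard_time_average(self, geom, fast_standard):
        trace = trace_retinal(build_world_interval(fast_standard, geom), geom)
        expected = (math.atan(3 / 77) - math.atan(3 / 117)) * ARCMIN_PER_RAD
        assert derive_retina_speed(trace) == pytest.approx(expected, abs=1e-6)
        assert derive_retina_speed(trace) == pytest.approx(45.75, abs=0.01)

    def test_slow_standard_time_average(self, geom, slow_standard):
        trace = trace_retinal(build_world_interval(slow_standard, geom), geom)
        assert derive_retina_speed(trace) == pytest.approx(22.13, abs=0.01)

    def test_constant_trace_returns_its_speed(self, geom):
        trace = build_retina_interval(47.6, 47.6, geom=geom)
        assert derive_retina_speed(trace) == pytest.approx(47.6, abs=1e-9)


class TestRenderStereo:
    def test_screen_plane_fixed_point(self, geom, fast_standard):
        """When the object sits in the screen plane each eye draws it at x_w."""
        traj = build_world_interval(fast_standard, geom)
        xs = render_stereo(traj, geom)
        assert xs.shape == (86, 2, 2)
        e = np.array(geom.eye_offsets[:2])
        for line_x in (-3.0, 3.0):
            pos = e + geom.viewing_distance_cm * (line_x - e) / geom.viewing_distance_cm
            np.testing.assert_allclose(pos, line_x, atol=1e-12)

    def test_zero_ipd_collapses_to_cyclopean(self):
        geom = ViewingGeometry(ipd_cm=0.0)
        traj = build_world_interval(SpeedChangeInterval(40.0, 40.0), geom)
        xs = render_stereo(traj, geom)
        np.testing.assert_allclose(xs[:, :, 0], xs[:, :, 1], atol=1e-12)
        t = np.arange(86) / 85
        cyclo = 97.0 * 3.0 / traj.z_of_t(t)
        np.testing.assert_allclose(xs[:, 1, 0], cyclo, rtol=1e-12)

    def test_disparity_grows_with_approach(self, geom, fast_standard):
        traj = build_world_interval(fast_standard, geom)
        xs = render_stereo(traj, geom)
        # angular disparity of the right line between the two eyes
        t = np.arange(86) / 85
        z = traj.z_of_t(t)
        e = np.array(geom.eye_offsets[:2])
        ang = np.arctan((3.0 - e[None, :]) / z[:, None])
        disparity = ang[:, 0] - ang[:, 1]
        assert disparity[-1] > disparity[0]

    def test_world_control_duplicates_left_eye(self, geom, fast_standard):
        traj = build_world_interval(fast_standard, geom)
        xs = render_stereo(traj, geom, world_control=True)
        np.testing.assert_array_equal(xs[:, :, 0], xs[:, :, 1])


class TestRecoverGeometry:
    def test_recovers_start_distance_and_offset(self, geom, fast_standard):
        trace = trace_retinal(build_world_interval(fast_standard, geom), geom)
        z0, x = recover_geometry(trace.a, trace.d, 40.0, 1.0)
        assert z0 == pytest.approx(117.0, abs=0.5)
        assert x == pytest.approx(3.0, abs=0.05)

    def test_recovers_slow_geometry_from_printed_speeds(self):
        z0, x = recover_geometry(18.0, 27.2, 20.0, 1.0)
        assert z0 == pytest.approx(107.0, abs=0.5)

    def test_inconsistent_inputs_rejected(self):
        with pytest.raises(ValueError):
            recover_geometry(50.0, 40.0, 40.0, 1.0)  # d < a
        with pytest.raises(ValueError):
            recover_geometry(-1.0, 40.0, 40.0, 1.0)


class TestConservation:
    @pytest.mark.parametrize("standard_v, step", [(40.0, 5.0), (20.0, 2.5)])
    def test_world_distance_conserved_across_levels(self, geom, standard_v, step):
        from stereospeed import level_ladder

        ref = standard_v * 1.0
        for rung in level_ladder(standard_v, step):
            iv = SpeedChangeInterval(rung.v_before, rung.v_after)
            assert iv.total_distance == pytest.approx(ref, abs=1e-9)
            traj = build_world_interval(iv, geom)
            assert traj.z0 == pytest.approx(geom.viewing_distance_cm + ref / 2)
            assert traj.z1 == pytest.approx(geom.viewing_distance_cm - ref / 2)

    def test_retina_displacement_conserved_across_levels(self, geom):
        from stereospeed.design import SpeedClass, _ladder_for, _retina_level_speeds

        for speed in SpeedClass:
            ladder = _ladder_for(speed)
            sb, sa = _retina_level_speeds(ladder[0], speed, geom)
            ref = 0.5 * sb + 0.5 * sa
            for rung in ladder:
                sb, sa = _retina_level_speeds(rung, speed, geom)
                assert 0.5 * sb + 0.5 * sa == pytest.approx(ref, abs=1e-9)
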