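import math

import numpy as np
import pytest

import flydetector as fd
from flydetector.scene_model import BarrierKinematics, TunnelScene
from flydetector.visual_params import (
    EyeState,
    cast_ray,
    geometric_flow_field,
    retinal_size,
    retinal_size_rate,
    rrev,
    visual_param_series,
)

MID = (0.5, 0.0, 0.14)


class TestCastRay:
    def test_side_wall(self, scene, kin_static):
        r, surface, v = cast_ray(scene, kin_static, MID, (0, 1, 0))
        assert r == pytest.approx(scene.width / 2)
        assert surface == "wall-left"
        assert np.allclose(v, 0)

    def test_through_gap(self, scene, kin_static):
        r, surface, _ = cast_ray(scene, kin_static, MID, (1, 0, 0))
        assert surface == "none" and math.isinf(r)

    def test_barrier_panel_distance_and_velocity(self, scene, kin_dynamic):
        origin = (0.5, 0.05, 0.14)
        r, surface, v = cast_ray(scene, kin_dynamic, origin, (1, 0, 0), t=0.5)
        assert surface == "barrier-left"
        assert r == pytest.approx(scene.barrier_plane_x - origin[0])
        # each edge carries half the opening rate
        assert abs(v[1]) == pytest.approx(kin_dynamic.vc / 2)

    def test_floor_and_ceiling(self, scene, kin_static):
        r, surface, _ = cast_ray(scene, kin_static, MID, (0, 0, -1))
        assert surface == "floor" and r == pytest.approx(0.14)
        r, surface, _ = cast_ray(scene, kin_static, MID, (0, 0, 1))
        assert surface == "ceiling" and r == pytest.approx(0.14)

    def test_outside_origin_rejected(self, scene, kin_static):
        with pytest.raises(ValueError):
            cast_ray(scene, kin_static, (-0.5, 0, 0.14), (1, 0, 0))

    def test_non_unit_direction_rejected(self, scene, kin_static):
        with pytest.raises(ValueError):
            cast_ray(scene, kin_static, MID, (2, 0, 0))


class TestFlowField:
    def test_static_eye_static_scene_is_zero(self, scene, kin_static):
        field = geometric_flow_field(scene, kin_static, EyeState(MID, (0, 0, 0)))
        assert field.magnitude.max() == 0.0

    def test_pure_rotation_distance_free(self, scene, kin_static):
        """At zero elevation the rotational flow magnitude is |omega| for
        every azimuth, independently of scene distances."""
        omega = 90.0
        eye = EyeState(MID, (0, 0, 0), yaw_rate_deg_s=omega)
        field = geometric_flow_field(scene, kin_static, eye)
        m = field.elevation_deg == 0.0
        assert np.allclose(field.magnitude[m], math.radians(omega), rtol=1e-9)
        # and identical in a differently-sized scene
        big = TunnelScene(length=3.0, width=0.5, height=0.5, barrier_plane_x=2.0)
        f2 = geometric_flow_field(big, kin_static, EyeState((1.0, 0, 0.25), (0, 0, 0), yaw_rate_deg_s=omega))
        np.testing.assert_allclose(field.vx, f2.vx, atol=1e-12)
        np.testing.assert_allclose(field.vy, f2.vy, atol=1e-12)

    def test_focus_of_expansion(self, scene, kin_static):
        eye = EyeState(MID, (1.0, 0, 0))
        field = geometric_flow_field(scene, kin_static, eye)
        at_heading = (field.azimuth_deg == 0.0) & (field.elevation_deg == 0.0)
        assert field.magnitude[at_heading] == pytest.approx(0.0, abs=1e-12)

    def test_distance_scaling_halves_flow(self, kin_static):
        """Doubling all scene distances halves every translational flow."""
        s1 = TunnelScene()
        s2 = TunnelScene(length=3.12, width=0.56, height=0.56, barrier_plane_x=2.52)
        k1 = BarrierKinematics.static(0.06)
        k2 = BarrierKinematics.static(0.12)
        f1 = geometric_flow_field(s1, k1, EyeState((0.5, 0, 0.14), (1, 0, 0)))
        f2 = geometric_flow_field(s2, k2, EyeState((1.0, 0, 0.28), (1, 0, 0)))
        m = np.isfinite(f1.r) & (f1.magnitude > 1e-12)
        np.testing.assert_allclose(f2.magnitude[m], f1.magnitude[m] / 2, rtol=1e-9)

    def test_linearity_in_motion_parameters(self, scene, kin_static):
        """field(T, omega) = field(T, 0) + field(0, omega) exactly."""
        ft = geometric_flow_field(scene, kin_static, EyeState(MID, (1.0, 0.2, 0)))
        fr = geometric_flow_field(scene, kin_static, EyeState(MID, (0, 0, 0), yaw_rate_deg_s=120.0))
        both = geometric_flow_field(
            scene, kin_static, EyeState(MID, (1.0, 0.2, 0), yaw_rate_deg_s=120.0)
        )
        np.testing.assert_allclose(both.vx, ft.vx + fr.vx, atol=1e-12)
        np.testing.assert_allclose(both.vy, ft.vy + fr.vy, atol=1e-12)

    def test_static_pose_dynamic_scene_flow_only_on_barrier(self, scene, kin_dynamic):
        """For a hovering bee all nonzero flow comes from the moving gap."""
        eye = EyeState((1.0, 0.0, 0.14), (0, 0, 0), time=0.3)
        field = geometric_flow_field(scene, kin_dynamic, eye)
        moving = field.magnitude > 1e-12
        assert moving.any()
        assert set(field.surface[moving]) <= {"barrier-left", "barrier-right"}

    def test_gap_sector_matches_retinal_size(self, scene):
        """The angular width of the gap ('none' sector ahead) in a horizontal
        flow slice agrees with gamma from the gap-edge bearings."""
        kin = BarrierKinematics.static(0.12)
        eye_pos = (0.9, 0.0, 0.14)
        spacing = 1.0
        field = geometric_flow_field(scene, kin, EyeState(eye_pos, (0, 0, 0)), spacing)
        horiz = field.elevation_deg == 0.0
        az = field.azimuth_deg[horiz]
        surf = field.surface[horiz]
        ahead = np.abs(az) <= 45.0
        gap_width_deg = spacing * np.sum(surf[ahead] == "none")
        gamma = retinal_size(
            (scene.barrier_plane_x, 0.06), eye_pos[:2], (scene.barrier_plane_x, -0.06)
        )
        assert abs(gap_width_deg - math.degrees(gamma)) <= spacing


class TestRetinalGeometry:
    def test_degenerate_gap(self):
        assert retinal_size((2, 1), (0, 0), (2, 1)) == 0.0

    def test_symmetric_example(self):
        gamma = retinal_size((2, 1), (0, 0), (2, -1))
        assert gamma == pytest.approx(2 * math.atan(0.5), rel=1e-9)

    def test_label_order_invariance(self):
        a, b, c = (2, 1), (0.3, -0.2), (2, -1)
        assert retinal_size(a, b, c) == pytest.approx(retinal_size(c, b, a))

    def test_closed_form_head_on(self):
        d, D = 0.1, 0.5
        gamma = retinal_size((1.0, d / 2), (1.0 - D, 0.0), (1.0, -d / 2))
        assert gamma == pytest.approx(2 * math.atan(d / (2 * D)), rel=1e-9)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            retinal_size((0, 0), (0, 0), (1, 1))

    def test_rate_linear_exact(self):
        t = np.linspace(0, 1, 11)
        assert np.allclose(retinal_size_rate(t, 0.3 * t), 0.3)

    def test_rate_constant_zero(self):
        t = np.linspace(0, 1, 11)
        assert np.allclose(retinal_size_rate(t, np.full_like(t, 0.2)), 0.0)

    def test_rate_needs_three_samples(self):
        with pytest.raises(ValueError):
            retinal_size_rate([0, 1], [0, 1])

    def test_rrev_zero_rate(self):
        val, defined = rrev(0.2, 0.0)
        assert defined and val == 0.0

    def test_rrev_undefined_below_eps(self):
        val, defined = rrev(1e-6, 0.1)
        assert not defined and math.isnan(val)

    def test_head_on_closed_form_and_limit(self):
        """gamma_dot = d*v/(D^2 + d^2/4); RREV -> v/D in the small-angle limit."""
        d, v = 0.1, 1.0
        ts = np.linspace(0.0, 0.3, 601)
        D = 0.5 - v * ts
        gamma = 2 * np.arctan(d / (2 * D))
        gdot = retinal_size_rate(ts, gamma)
        k = 300  # interior sample, D = 0.2
        expected = d * v / (D[k] ** 2 + d**2 / 4)
        assert gdot[k] == pytest.approx(expected, rel=0.01)
        rv, defined = rrev(gamma, gdot)
        assert defined[k]
        # at D = 0.2, d/D = 0.5: not yet small-angle; check the far regime
        far_D = 2.0
        g_far = 2 * math.atan(d / (2 * far_D))
        gd_far = d * v / (far_D**2 + d**2 / 4)
        assert gd_far / g_far == pytest.approx(v / far_D, rel=0.01)


class TestVisualParamSeries:
    def test_series_on_approach(self, scene, kin_static):
        v = 0.5
        ts = np.linspace(0.0, 1.0, 164)
        xs = 0.4 + v * ts
        pos = np.column_stack([xs, np.zeros_like(ts)])
        series = visual_param_series(scene, kin_static, ts, pos)
        assert np.all(np.diff(series.gamma_rad) > 0)  # looms while approaching
        assert np.all(series.defined)
        D = scene.barrier_plane_x - xs
        expected = 2 * np.arctan(kin_static.d_min / (2 * D))
        np.testing.assert_allclose(series.gamma_rad, expected, rtol=1e-9)

    def test_csv_columns(self, tmp_path, scene, kin_dynamic):
        ts = np.linspace(0, 0.5, 50)
        pos = np.column_stack([0.5 + 0.3 * ts, 0.01 * np.sin(ts)])
        series = visual_param_series(scene, kin_dynamic, ts, pos)
        series.to_csv(tmp_path / "params.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "params.csv")
        assert list(df.columns) == ["time_s", "gamma_rad", "gamma_dot", "rrev", "defined_flag"]
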