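"""Ego-motion flow simulator: geometry, kinematics, dataset sampling."""

import numpy as np
import pytest

from artflow.flow import (
    CameraModel,
    DatasetSpec,
    EgoMotion,
    advance_scene,
    analytic_flow,
    generate_dataset,
    heading_to_translation,
    label_matrix,
    make_scene,
    render_sequence,
)

SQ2 = np.sqrt(2) / 2


class TestHeadingToTranslation:
    @pytest.mark.parametrize(
        "az, el, speed, expected",
        [
            (0, 0, 3, (0, 0, 3)),  # straight ahead
            (90, 0, 1, (1, 0, 0)),  # pure rightward
            (45, 0, 1, (SQ2, 0, SQ2)),  # spherical-to-Cartesian closed form
            (0, 90, 1, (0, 1, 0)),  # straight up
            (0, -30, 2, (0, -1, np.sqrt(3))),
        ],
    )
    def test_closed_form(self, az, el, speed, expected):
        np.testing.assert_allclose(
            heading_to_translation(az, el, speed), expected, atol=1e-12
        )

    def test_norm_equals_speed(self, rng):
        for _ in range(20):
            az, el = rng.uniform(-89, 89, 2)
            v = heading_to_translation(az, el, 3.0)
            assert np.linalg.norm(v) == pytest.approx(3.0)


class TestMakeScene:
    def test_cloud_counts_and_depths(self, camera):
        scene = make_scene("cloud_T", camera, np.random.default_rng(0))
        assert scene.n_dots == 2000
        assert scene.points[:, 2].min() >= 1.0
        assert scene.points[:, 2].max() <= 50.0

    def test_ground_dots_at_eye_height(self, camera):
        scene = make_scene("ground_T", camera, np.random.default_rng(0))
        np.testing.assert_allclose(scene.points[:, 1], -1.61, atol=1e-9)
        assert scene.points[:, 2].min() >= 1.0
        assert scene.points[:, 2].max() <= 50.0

    def test_dots_inside_frustum(self, camera):
        for env in ("cloud_T", "ground_T"):
            scene = make_scene(env, camera, np.random.default_rng(3))
            x, y, _, _ = analytic_flow(scene.points, EgoMotion(), camera)
            assert np.all(np.abs(x) <= camera.width / 2)
            assert np.all(np.abs(y) <= camera.height / 2)

    def test_same_seed_identical(self, camera):
        a = make_scene("cloud_T", camera, np.random.default_rng(5))
        b = make_scene("cloud_T", camera, np.random.default_rng(5))
        np.testing.assert_array_equal(a.points, b.points)


class TestAnalyticFlow:
    def test_foe_singularity_on_axis(self, camera):
        """Pure forward translation: a point on the optical axis has no flow."""
        ego = EgoMotion(0, 0, 3.0)
        _, _, _, speed = analytic_flow([[0, 0, 10.0]], ego, camera)
        assert speed[0] == pytest.approx(0.0, abs=1e-12)

    def test_translational_field_is_radial(self, camera, rng):
        """Every T-only flow vector points away from the FoE, collinearly."""
        ego = EgoMotion(20.0, -10.0, 3.0)
        t = ego.translation
        f = camera.focal_length_px
        foe = np.array([f * t[0] / t[2], f * t[1] / t[2]])
        pts = np.column_stack(
            [rng.uniform(-5, 5, 200), rng.uniform(-5, 5, 200), rng.uniform(1, 50, 200)]
        )
        x, y, direction, speed = analytic_flow(pts, ego, camera)
        radial = np.arctan2(y - foe[1], x - foe[0])
        moving = speed > 1e-9
        dev = np.angle(np.exp(1j * (direction[moving] - radial[moving])))
        assert np.abs(dev).max() < 1e-9

    def test_pure_yaw_at_principal_point(self, camera):
        """Rotational speed at the image center is f*omega px/frame, any depth."""
        w = 7.0  # deg/s yaw
        ego = EgoMotion(0, 0, 0.0, rotation_rates=(0.0, w, 0.0))
        for z in (2.0, 20.0):
            _, _, direction, speed = analytic_flow([[0, 0, z]], ego, camera)
            px_per_s = speed[0] / camera.deg_per_px
            assert px_per_s == pytest.approx(
                camera.focal_length_px * np.deg2rad(w), rel=1e-12
            )
            assert np.cos(direction[0]) == pytest.approx(-1.0)  # leftward image motion

    def test_rotational_flow_depth_independent(self, camera, rng):
        ego = EgoMotion(0, 0, 0.0, rotation_rates=(3.0, -5.0, 2.0))
        xy = np.column_stack([rng.uniform(-4, 4, 100), rng.uniform(-4, 4, 100)])
        near = np.column_stack([xy * 2.0, np.full(100, 2.0)])
        far = np.column_stack([xy * 40.0, np.full(100, 40.0)])
        ra = analytic_flow(near, ego, camera)
        rb = analytic_flow(far, ego, camera)
        np.testing.assert_allclose(ra[2], rb[2], atol=1e-9)
        np.testing.assert_allclose(ra[3], rb[3], atol=1e-9)

    def test_first_order_additivity(self, camera, rng):
        """flow(T+R) = flow(T) + flow(R) at identical dot positions."""
        t_only = EgoMotion(15, 5, 3.0)
        r_only = EgoMotion(0, 0, 0.0, rotation_rates=(2.0, 6.0, -3.0))
        both = EgoMotion(15, 5, 3.0, rotation_rates=(2.0, 6.0, -3.0))
        pts = np.column_stack(
            [rng.uniform(-10, 10, 50), rng.uniform(-10, 10, 50), rng.uniform(1, 50, 50)]
        )
        def uv(ego):
            _, _, d, s = analytic_flow(pts, ego, camera)
            return s * np.cos(d), s * np.sin(d)
        ut, vt = uv(t_only)
        ur, vr = uv(r_only)
        ub, vb = uv(both)
        np.testing.assert_allclose(ub, ut + ur, atol=1e-9)
        np.testing.assert_allclose(vb, vt + vr, atol=1e-9)

    def test_behind_camera_rejected(self, camera):
        with pytest.raises(ValueError):
            analytic_flow([[0, 0, -1.0]], EgoMotion(), camera)


class TestAdvanceScene:
    def test_zero_motion_unchanged(self, camera):
        scene = make_scene("cloud_T", camera, np.random.default_rng(1))
        ego = EgoMotion(0, 0, 0.0)
        out = advance_scene(scene, ego, 1 / 30, camera, np.random.default_rng(2))
        np.testing.assert_array_equal(out.points, scene.points)

    def test_near_dot_respawned_count_conserved(self, camera):
        """A dot at Z = 1.05 m exits the near plane under 3 m/s forward motion
        (0.1 m per frame) within a frame and is replaced by a fresh draw."""
        scene = make_scene("cloud_T", camera, np.random.default_rng(1))
        pts = scene.points.copy()
        pts[0] = [0.1, 0.1, 1.05]
        scene.points = pts
        ego = EgoMotion(0, 0, 3.0)
        rng = np.random.default_rng(9)
        for _ in range(2):
            scene = advance_scene(scene, ego, 1 / 30, camera, rng)
        assert scene.n_dots == 2000
        assert scene.points[:, 2].min() >= 1.0

    def test_ground_dots_stay_on_plane(self, camera):
        scene = make_scene("ground_T", camera, np.random.default_rng(4))
        ego = EgoMotion(30.0, -20.0, 3.0)
        rng = np.random.default_rng(5)
        for _ in range(9):
            scene = advance_scene(scene, ego, 1 / 30, camera, rng)
        # all dots on the tracked plane (y = -current offset for a level camera)
        np.testing.assert_allclose(scene.points[:, 1], -scene.plane_offset, atol=1e-9)


class TestRenderSequence:
    def test_t_only_foe_fixed_every_frame(self, camera):
        ego = EgoMotion(25.0, 12.0, 3.0)
        t = ego.translation
        f = camera.focal_length_px
        foe = np.array([f * t[0] / t[2], f * t[1] / t[2]])
        seq = render_sequence(ego, "cloud_T", camera, np.random.default_rng(6))
        assert seq.n_frames == 10
        for fr in seq.frames:
            radial = np.arctan2(fr.y - foe[1], fr.x - foe[0])
            dev = np.angle(np.exp(1j * (fr.direction - radial)))
            assert np.abs(dev).max() < 1e-9

    def test_frame_vector_counts(self, camera):
        seq = render_sequence(EgoMotion(10, 5, 3.0), "cloud_T", camera,
                              np.random.default_rng(8))
        for fr in seq.frames:
            assert len(fr) <= 2000
            assert len(fr) > 1900  # only exactly-stationary dots are dropped
            assert np.all(fr.speed > 0)


class TestGenerateDataset:
    def test_default_sizes_and_label_ranges(self, tiny_cloud):
        spec, train, test = tiny_cloud
        assert (len(train), len(test)) == (spec.n_train, spec.n_test)
        lab = label_matrix(train + test, "heading")
        assert lab.min() > -45 and lab.max() < 45

    def test_table_default_sizes(self):
        assert (DatasetSpec("cloud_T").n_train, DatasetSpec("cloud_T").n_test) == (500, 250)
        assert (DatasetSpec("ground_T").n_train, DatasetSpec("ground_T").n_test) == (500, 250)
        assert (DatasetSpec("cloud_TR").n_train, DatasetSpec("cloud_TR").n_test) == (1000, 500)

    def test_rotation_magnitudes_in_range(self):
        spec = DatasetSpec(environment="cloud_TR", n_train=15, n_test=5, seed=3)
        train, test = generate_dataset(spec)
        mags = [np.linalg.norm(s.labels.rotation_rates) for s in train + test]
        assert min(mags) >= 1.0 and max(mags) <= 10.0

    def test_determinism(self):
        spec = DatasetSpec(environment="cloud_T", n_train=3, n_test=2, seed=77)
        a_train, _ = generate_dataset(spec)
        b_train, _ = generate_dataset(spec)
        for a, b in zip(a_train, b_train):
            np.testing.assert_array_equal(a.frames[0].x, b.frames[0].x)
            np.testing.assert_array_equal(a.frames[-1].speed, b.frames[-1].speed)
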