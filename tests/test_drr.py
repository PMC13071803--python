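"""Ray-cast DRR correctness: analytic integrals, projective geometry."""

import numpy as np
import pytest

from bvrpose.camera import make_camera, project_point, read_calibration, write_calibration
from bvrpose.drr import camera_ray_grid, projected_bbox, render_drr
from bvrpose.geometry import RigidTransform
from bvrpose.phantom import make_camera_rig
from bvrpose.volume import VoxelVolume, centered_volume


class TestRenderDrr:
    def test_zero_volume_gives_zero_image(self, face_on_camera):
        vol = centered_volume(np.zeros((16, 16, 16), np.float32), 1.0)
        img = render_drr(vol, RigidTransform.identity(), face_on_camera)
        assert np.abs(img).max() == 0.0

    def test_uniform_cube_chord_length(self, face_on_camera, uniform_cube):
        cube, mu, side = uniform_cube
        step = 0.5
        img = render_drr(cube, RigidTransform.identity(), face_on_camera, step_mm=step)
        centre_px = img[32, 32]  # principal ray, perpendicular to the face
        assert abs(centre_px - mu * side) <= 2 * step * mu

    def test_linearity_in_attenuation(self, face_on_camera, uniform_cube):
        cube, mu, _ = uniform_cube
        img1 = render_drr(cube, RigidTransform.identity(), face_on_camera, step_mm=0.5)
        scaled = VoxelVolume(cube.intensities * 3.0, cube.spacing, cube.origin)
        img3 = render_drr(scaled, RigidTransform.identity(), face_on_camera, step_mm=0.5)
        assert np.abs(img3 - 3 * img1).max() <= 1e-9 * max(img1.max() * 3, 1)

    def test_step_halving_convergence(self, face_on_camera, uniform_cube):
        cube, _, _ = uniform_cube
        a = render_drr(cube, RigidTransform.identity(), face_on_camera, step_mm=0.5)
        b = render_drr(cube, RigidTransform.identity(), face_on_camera, step_mm=0.25)
        assert np.abs(a - b).max() / a.max() < 0.01

    def test_mirror_symmetry(self, face_on_camera):
        rng = np.random.default_rng(0)
        arr = rng.random((20, 20, 20)).astype(np.float32)
        vol = centered_volume(arr, 1.0)
        mirrored = centered_volume(arr[::-1].copy(), 1.0)
        img = render_drr(vol, RigidTransform.identity(), face_on_camera, step_mm=0.5)
        img_m = render_drr(mirrored, RigidTransform.identity(), face_on_camera, step_mm=0.5)
        # world x maps to image columns for this face-on camera
        assert np.abs(img_m - img[:, ::-1]).max() < 0.02 * img.max()

    def test_nonpositive_step_rejected(self, face_on_camera, uniform_cube):
        with pytest.raises(ValueError):
            render_drr(uniform_cube[0], RigidTransform.identity(), face_on_camera, step_mm=0.0)

    def test_rigid_consistency_pose_vs_resampled_volume(self, face_on_camera):
        # rendering V at pose T must equal rendering the T-moved volume at
        # identity when the move is expressed through origin/direction
        rng = np.random.default_rng(5)
        vol = centered_volume((rng.random((18, 18, 18)) ** 2).astype(np.float32), 1.0)
        pose = RigidTransform.from_rotvec_deg([12, -9, 30], [4, 2, -6])
        moved = VoxelVolume(
            vol.intensities, vol.spacing, pose.apply(vol.origin),
            pose.rotation @ vol.direction,
        )
        a = render_drr(vol, pose, face_on_camera, step_mm=0.5)
        b = render_drr(moved, RigidTransform.identity(), face_on_camera, step_mm=0.5)
        assert np.abs(a - b).max() < 1e-9 * max(a.max(), 1)

    def test_ray_grid_cache_is_equivalent(self, face_on_camera, uniform_cube):
        cube, _, _ = uniform_cube
        pose = RigidTransform.from_rotvec_deg([5, 10, 0], [3, 0, 1])
        plain = render_drr(cube, pose, face_on_camera)
        cached = render_drr(
            cube, pose, face_on_camera, ray_grid=camera_ray_grid(face_on_camera)
        )
        assert np.array_equal(plain, cached)

    def test_bbox_restriction_matches_full_cast(self, face_on_camera, uniform_cube):
        cube, _, _ = uniform_cube
        full = render_drr(cube, RigidTransform.identity(), face_on_camera)
        bbox = projected_bbox(cube, RigidTransform.identity(), face_on_camera)
        r0, r1, c0, c1 = bbox
        outside = full.copy()
        outside[r0:r1, c0:c1] = 0.0
        assert np.abs(outside).max() == 0.0  # nothing rendered outside the bbox


class TestCameraGeometry:
    def test_source_is_projection_null_space(self):
        cams = make_camera_rig(image_size=(64, 64), pixel_pitch_mm=2.0)
        for cam in cams:
            h = cam.projection @ np.append(cam.source, 1.0)
            assert np.abs(h).max() < 1e-8

    def test_world_origin_projects_to_principal_point(self):
        cams = make_camera_rig(image_size=(65, 65), pixel_pitch_mm=2.0)
        for cam in cams:
            uv, behind = project_point(cam, np.zeros(3))
            assert not behind
            assert np.allclose(uv, cam.principal_point, atol=1e-9)
            assert np.allclose(uv, [32.0, 32.0], atol=1e-9)

    def test_rig_subtends_requested_angle(self):
        for angle in (60.0, 90.0):
            a, b = make_camera_rig(
                image_size=(64, 64), pixel_pitch_mm=2.0, inter_view_angle_deg=angle
            )
            ca = a.source / np.linalg.norm(a.source)
            cb = b.source / np.linalg.norm(b.source)
            assert abs(np.degrees(np.arccos(ca @ cb)) - angle) < 1e-9

    def test_point_on_principal_ray_hits_principal_point(self, face_on_camera):
        cam = face_on_camera
        target = cam.source + 2.5 * (np.zeros(3) - cam.source)
        uv, _ = project_point(cam, target)
        assert np.allclose(uv, cam.principal_point, atol=1e-9)

    def test_behind_camera_flagged(self, face_on_camera):
        cam = face_on_camera
        behind_point = cam.source - np.array([0.0, 10.0, 0.0])
        _, behind = project_point(cam, behind_point)
        assert behind

    def test_project_backproject_ray_consistency(self, face_on_camera, rng):
        cam = face_on_camera
        for _ in range(20):
            p = rng.uniform(-40, 40, 3)
            uv, behind = project_point(cam, p)
            assert not behind
            d = cam.ray_directions(uv)[0]
            # distance from p to the ray through the source
            v = p - cam.source
            dist = np.linalg.norm(v - (v @ d) * d)
            assert dist < 1e-6

    def test_resize_preserves_physical_pointing(self, face_on_camera):
        cam = face_on_camera
        small = cam.resize((13, 13))
        p = np.array([7.0, -3.0, 11.0])
        uv_big, _ = project_point(cam, p)
        uv_small, _ = project_point(small, p)
        scale = 13 / 65
        assert np.allclose((uv_big + 0.5) * scale - 0.5, uv_small, atol=1e-9)

    def test_decimate_pixel_centres_match_kept_native_pixels(self, face_on_camera):
        cam = face_on_camera
        # 65 not divisible; build a 64-pixel camera for decimation
        cam64 = cam.resize((64, 64))
        dec = cam64.decimate(4)
        p = np.array([5.0, 2.0, -9.0])
        uv_native, _ = project_point(cam64, p)
        uv_dec, _ = project_point(dec, p)
        assert np.allclose(uv_dec * 4 + 2, uv_native, atol=1e-9)


class TestCalibrationIo:
    def test_matrix_dialect_roundtrip(self, tmp_path, face_on_camera):
        path = tmp_path / "cam.txt"
        write_calibration(path, face_on_camera)
        cam = read_calibration(path)
        assert cam.image_size == face_on_camera.image_size
        assert np.allclose(cam.projection, face_on_camera.projection, atol=1e-12)

    def test_geometry_dialect(self, tmp_path, face_on_camera):
        path = tmp_path / "cam_geom.txt"
        path.write_text(
            "source = 0 -1000 0\nlook_at = 0 0 0\nup = 0 0 1\n"
            "rows = 65\ncols = 65\npixel_pitch_mm = 1.0\n"
            "source_to_detector_mm = 1200\n"
        )
        cam = read_calibration(path)
        assert np.allclose(cam.projection, face_on_camera.projection, atol=1e-9)
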