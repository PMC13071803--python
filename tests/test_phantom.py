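"""Synthetic trial generation: bones, rig, trajectories, noisy captures."""

import numpy as np
import pytest

from bvrpose.geometry import inertial_frame
from bvrpose.imageops import downsample_bicubic
from bvrpose.phantom import (
    NoiseSpec,
    make_bone_volume,
    make_scene,
    make_trajectory,
    render_clean_integral,
    render_trial,
)
from bvrpose.helical import pose_error


class TestBoneVolumes:
    @pytest.mark.parametrize("kind", ["isolated", "enclosed", "long-bone"])
    def test_deterministic_given_seed(self, kind):
        a = make_bone_volume(kind, (24, 24, 24), 1.0, seed=7)
        b = make_bone_volume(kind, (24, 24, 24), 1.0, seed=7)
        assert np.array_equal(a.intensities, b.intensities)
        c = make_bone_volume(kind, (24, 24, 24), 1.0, seed=8)
        assert not np.array_equal(a.intensities, c.intensities)

    def test_shell_brighter_than_interior(self):
        vol = make_bone_volume("isolated", (32, 32, 32), 1.0, seed=1).intensities
        from bvrpose.phantom import MU_TRABECULAR

        nz = vol[vol > 0]
        # the cortical shell must clearly exceed the (textured) interior
        assert nz.max() > 2.5 * np.median(nz)
        assert np.median(nz) < 2.5 * MU_TRABECULAR

    def test_positive_mass_and_inertial_frame(self):
        for kind in ("isolated", "enclosed", "long-bone"):
            vol = make_bone_volume(kind, (24, 24, 24), 1.0, seed=0)
            assert vol.intensities.sum() > 0
            inertial_frame(vol)  # must not raise

    def test_long_bone_elongation(self):
        vol = make_bone_volume("long-bone", (32, 32, 64), 1.0, seed=2)
        nz = np.nonzero(vol.intensities)
        spans = [a.max() - a.min() + 1 for a in nz]
        assert spans[2] >= 3 * min(spans[0], spans[1])

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            make_bone_volume("isolated", (8, 8, 8), 1.0)


class TestTrajectory:
    def test_frame_count_and_determinism(self):
        t1 = make_trajectory(35, seed=4)
        t2 = make_trajectory(35, seed=4)
        for name in t1:
            assert len(t1[name]) == 35
            for a, b in zip(t1[name], t2[name]):
                assert np.array_equal(a.matrix, b.matrix)

    def test_zero_amplitude_freezes_motion(self):
        traj = make_trajectory(10, amplitude_mm=0.0, amplitude_deg=0.0, seed=0)
        for poses in traj.values():
            for p in poses[1:]:
                assert p.almost_equal(poses[0], tol=1e-12)

    def test_adjacent_frame_change_bounded(self):
        traj = make_trajectory(8, seed=1)
        for poses in traj.values():
            for a, b in zip(poses, poses[1:]):
                err = pose_error(a, b)
                assert err.phi_deg < 3.0
                assert np.linalg.norm(b.translation - a.translation) < 5.0

    def test_long_bone_exit_shifts_edge_frames(self):
        base = make_trajectory(20, seed=0)
        exited = make_trajectory(20, seed=0, long_bone_exit=True)
        dz = [
            e.translation[2] - b.translation[2]
            for b, e in zip(base["tibia"], exited["tibia"])
        ]
        assert dz[0] > 10.0 and dz[-1] > 10.0  # pushed out at the ends
        assert abs(dz[10]) < 1e-9  # untouched mid-motion
        for b, e in zip(base["talus"], exited["talus"]):
            assert b.almost_equal(e)


class TestRenderTrial:
    def test_noise_free_empty_scene_is_flat(self):
        scene = make_scene(
            bone_names=(), image_size=(32, 32), n_frames=1,
            noise=NoiseSpec(enabled=False), soft_tissue=False, seed=0,
        )
        frames = render_trial(scene)
        for img in frames[0].images:
            assert np.allclose(img, scene.noise.photon_scale)

    def test_counts_match_beer_lambert_of_integral(self, tiny_clean_scene):
        scene, frames = tiny_clean_scene
        integral = render_clean_integral(scene, 0, scene.cameras[0])
        expected = scene.noise.photon_scale * np.exp(-integral)
        assert np.allclose(frames[0].images[0], expected, rtol=1e-12)

    def test_deterministic_given_seed(self):
        kwargs = dict(bone_names=("talus",), image_size=(48, 48), volume_size=24,
                      n_frames=2, seed=11)
        a = render_trial(make_scene(**kwargs))
        b = render_trial(make_scene(**kwargs))
        for fa, fb in zip(a, b):
            for ia, ib in zip(fa.images, fb.images):
                assert np.array_equal(ia, ib)

    def test_downsampling_reduces_noise_variance(self):
        # Monte-Carlo over noise draws: per-pixel variance at native
        # resolution exceeds that of the 4x bicubic-downsampled images
        base = make_scene(bone_names=("talus",), image_size=(64, 64),
                          volume_size=24, n_frames=1, seed=5)
        clean = render_clean_integral(base, 0, base.cameras[0])
        counts = base.noise.photon_scale * np.exp(-clean)
        rng = np.random.default_rng(123)
        full, down = [], []
        for _ in range(100):
            noisy = rng.poisson(counts) + rng.normal(0, base.noise.read_sigma, counts.shape)
            noisy = np.maximum(noisy, 0.0)
            full.append(noisy)
            down.append(downsample_bicubic(noisy, (16, 16)))
        v_full = np.var(np.stack(full), axis=0).mean()
        v_down = np.var(np.stack(down), axis=0).mean()
        assert v_full > 4 * v_down

    def test_model_volumes_are_degraded_copies(self):
        scene = make_scene(bone_names=("talus",), image_size=(32, 32),
                           volume_size=24, n_frames=1, seed=2)
        truth = scene.bones["talus"].intensities
        model = scene.model_volume("talus").intensities
        assert model.shape == truth.shape
        assert not np.array_equal(model, truth)
        # blurring preserves total attenuation mass approximately
        assert model.sum() == pytest.approx(truth.sum(), rel=0.05)


class TestNoiseSpec:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(photon_scale=0.0)
        with pytest.raises(ValueError):
            NoiseSpec(read_sigma=-1.0)
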