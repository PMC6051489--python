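"""Template selection, intensity matching and rigid registration recovery."""

import numpy as np
import pytest

from pvr import (
    ImageVolume,
    InvalidParameterError,
    MotionSpec,
    RigidTransform3D,
    StackSpec,
    apply_motion,
    match_intensities,
    register_patch_to_volume,
    register_volume_3d,
    sample_interleaved_stack,
    select_template_stack,
)
from pvr.geometry import resample
from pvr.pipeline import make_psfs
from pvr.registration import foreground_median, normalized_cc, recenter_rigid
from pvr.patches import extract_square_patches


class TestTemplateSelection:
    def test_single_stack(self, phantom48):
        assert select_template_stack([phantom48]) == 0

    def test_tie_breaks_to_lowest_index(self, phantom48):
        assert select_template_stack([phantom48, phantom48.copy_geometry()]) == 0

    def test_noisy_stack_loses(self, phantom48, rng):
        clean = sample_interleaved_stack(phantom48, phantom48, StackSpec())
        noisy = clean.copy_geometry()
        noisy.voxels[:, :, ::2] = rng.random(noisy.voxels[:, :, ::2].shape) * 800
        assert select_template_stack([noisy, clean]) == 1

    def test_empty_rejected(self):
        with pytest.raises(InvalidParameterError):
            select_template_stack([])


class TestIntensityMatching:
    def test_template_unchanged(self, phantom48):
        out = match_intensities([phantom48, phantom48.copy_geometry()], 0)
        assert np.array_equal(out[0].voxels, phantom48.voxels)

    def test_exact_gain_recovered(self, phantom48):
        doubled = phantom48.copy_geometry(phantom48.voxels * 2.0)
        out = match_intensities([phantom48, doubled], 0)
        assert np.allclose(out[1].voxels, phantom48.voxels, atol=1e-9)

    def test_random_gains_equalize_foreground_medians(self, phantom48, rng):
        gains = rng.uniform(0.5, 2.0, 5)
        stacks = [phantom48.copy_geometry(phantom48.voxels * g) for g in gains]
        out = match_intensities(stacks, 0)
        ref = foreground_median(out[0])
        for s in out[1:]:
            assert abs(foreground_median(s) - ref) < 1e-6

    def test_all_zero_stack_rejected(self, phantom48):
        zero = phantom48.copy_geometry(np.zeros(phantom48.shape))
        with pytest.raises(InvalidParameterError):
            match_intensities([phantom48, zero], 0)


class TestVolumeRegistration:
    def test_identity_recovered_for_identical_volumes(self, phantom48):
        res = register_volume_3d(phantom48, phantom48)
        p = res.transform.parameters()
        assert np.abs(p[:3]).max() < 0.1      # degrees
        assert np.abs(p[3:]).max() < 0.1      # mm

    def test_known_translation_recovered(self, phantom48):
        t_true = (3.0, -2.0, 4.0)
        moving = resample(phantom48, RigidTransform3D(translation=t_true), phantom48)
        # moving(x) = fixed(x + t): the aligning pull transform is x - t
        res = register_volume_3d(moving, phantom48)
        assert np.abs(res.transform.parameters()[3:] - np.negative(t_true)).max() < 0.5

    def test_known_rotation_recovered(self, phantom48):
        lo, hi = phantom48.world_bounds()
        center = (lo + hi) / 2
        rot = RigidTransform3D(rotation=(0, 0, 5.0), center=center)
        moving = resample(phantom48, rot, phantom48)
        res = register_volume_3d(moving, phantom48)
        assert abs(res.transform.rotation[2] + 5.0) < 0.5
        assert np.abs(res.transform.rotation[:2]).max() < 0.5

    def test_inverse_consistency(self, phantom48):
        spec = MotionSpec("rigid_translation", d_x=4.0)
        moved = apply_motion(phantom48, spec)
        ab = register_volume_3d(moved, phantom48).transform
        ba = register_volume_3d(phantom48, moved).transform
        composed = ab.compose(ba).as_matrix()
        assert np.abs(composed[:3, 3]).max() < 0.6
        assert np.abs(composed[:3, :3] - np.eye(3)).max() < 0.02


@pytest.fixture(scope="module")
def patch_setup():
    from pvr import make_phantom

    phantom = make_phantom((48, 48, 48), seed=21)
    stack = sample_interleaved_stack(phantom, phantom, StackSpec())
    psf = make_psfs([stack])[0]
    return phantom, stack, psf


class TestPatchRegistration:
    def test_warm_start_is_kept_at_optimum(self, patch_setup):
        phantom, stack, psf = patch_setup
        patch = extract_square_patches(stack.voxels[:, :, 8], a=24, stride=24,
                                       slice_index=8)[1]
        res = register_patch_to_volume(patch, phantom, stack, psf)
        assert res.converged
        p = res.transform.parameters()
        assert np.abs(p[:3]).max() < 0.3
        assert np.abs(p[3:]).max() < 0.3

    def test_known_displacement_recovered(self, patch_setup):
        phantom, stack, psf = patch_setup
        patch = extract_square_patches(stack.voxels[:, :, 8], a=24, stride=24,
                                       slice_index=8)[1]
        true = RigidTransform3D(translation=(2.0, 0.0, 0.0))
        patch.transform = RigidTransform3D()
        # shift the volume so the optimum is a known pull translation
        shifted = resample(phantom, true, phantom)
        res = register_patch_to_volume(patch, shifted, stack, psf, step0=3.0,
                                       effort="thorough")
        assert res.converged
        # residual displacement at the patch centroid after undoing the truth
        from pvr.forward import patch_pixel_world
        centroid = patch_pixel_world(patch, stack).mean(axis=0)
        delta = res.transform.as_matrix() @ true.inverse().as_matrix()
        moved = delta[:3, :3] @ centroid + delta[:3, 3]
        assert np.linalg.norm(moved - centroid) < 0.6

    def test_similarity_never_below_warm_start(self, patch_setup, rng):
        phantom, stack, psf = patch_setup
        patches = extract_square_patches(stack.voxels[:, :, 10], a=16, stride=16,
                                         slice_index=10)
        from pvr.registration import rigid_from_params
        for patch in patches[:4]:
            warm = RigidTransform3D(rotation=rng.uniform(-2, 2, 3),
                                    translation=rng.uniform(-2, 2, 3))
            patch.transform = warm
            res = register_patch_to_volume(patch, phantom, stack, psf)
            if not res.converged:
                continue
            # evaluate both poses with the registration similarity itself
            base = register_patch_to_volume(
                patch, phantom, stack, psf, max_evals=1)
            assert res.similarity >= base.similarity - 1e-9

    def test_degenerate_patch_skipped(self, patch_setup):
        phantom, stack, psf = patch_setup
        patch = extract_square_patches(np.zeros((38, 38)), a=16, stride=16,
                                       slice_index=0)[0]
        res = register_patch_to_volume(patch, phantom, stack, psf)
        assert not res.converged
        assert res.transform is patch.transform

    def test_cc_affine_intensity_invariance(self, rng):
        a = rng.random(500)
        b = rng.random(500)
        assert abs(normalized_cc(a, b) - normalized_cc(3.0 * a + 5.0, b)) < 1e-9
        assert abs(normalized_cc(a, b) - normalized_cc(a, 0.5 * b - 2.0)) < 1e-9


class TestParameterRecoveryBatch:
    def test_translation_perturbations_recovered(self, patch_setup, rng):
        """Small rigid translations are pulled back to the optimum pose."""
        phantom, stack, psf = patch_setup
        patches = extract_square_patches(stack.voxels[:, :, 9], a=24, stride=12,
                                         slice_index=9)
        good = 0
        usable = [p for p in patches if p.values.std() > 40][:6]
        from pvr.forward import patch_pixel_world
        for patch in usable:
            centroid = patch_pixel_world(patch, stack).mean(axis=0)
            trans = rng.uniform(-3, 3, 3)
            patch.transform = RigidTransform3D(translation=trans, center=centroid)
            res = register_patch_to_volume(patch, phantom, stack, psf, step0=3.0)
            if not res.converged:
                continue
            # the optimum is the identity pose
            disp = np.linalg.norm(res.transform.apply(centroid) - centroid)
            if disp < 1.25:
                good += 1
        assert good >= len(usable) - 1
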