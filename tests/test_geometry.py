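"""World/voxel geometry, rigid and affine transforms, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvr import (
    AffineTransform3D,
    ImageVolume,
    InvalidParameterError,
    InvalidTransformError,
    RigidTransform3D,
    resample,
)
from pvr.geometry import random_rigid, rigid_from_matrix, load_transform, save_transform


def make_volume(shape=(8, 8, 8), spacing=(1.25, 1.25, 2.5), origin=(1.0, -2.0, 3.0)):
    rng = np.random.default_rng(0)
    return ImageVolume(rng.random(shape) * 100, spacing, origin)


class TestWorldVoxelMapping:
    def test_origin_maps_to_zero_index(self):
        vol = make_volume()
        assert np.allclose(vol.world_to_voxel(vol.origin), (0, 0, 0))

    def test_forward_map_inverts(self):
        vol = make_volume()
        point = vol.origin + vol.direction @ (vol.spacing * np.array([2, 3, 4]))
        assert np.allclose(vol.world_to_voxel(point), (2, 3, 4), atol=1e-9)

    def test_round_trip_many_points(self, rng):
        vol = make_volume()
        idx = rng.uniform(-5, 20, size=(100, 3))
        back = vol.world_to_voxel(vol.voxel_to_world(idx))
        assert np.abs(back - idx).max() < 1e-9

    def test_rejects_bad_spacing_and_direction(self):
        with pytest.raises(InvalidParameterError):
            ImageVolume(np.zeros((4, 4, 4)), (1, -1, 1), (0, 0, 0))
        with pytest.raises(InvalidParameterError):
            ImageVolume(np.zeros((4, 4, 4)), (1, 1, 1), (0, 0, 0),
                        direction=np.ones((3, 3)))


class TestRigidTransform:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_inverse_round_trips_points(self, seed):
        rng = np.random.default_rng(seed)
        t = random_rigid(rng, center=rng.uniform(-10, 10, 3))
        pts = rng.uniform(-50, 50, (20, 3))
        back = t.inverse().apply(t.apply(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_compose_with_inverse_is_identity(self, rng):
        for _ in range(100):
            t = random_rigid(rng, center=rng.uniform(-10, 10, 3))
            m = t.compose(t.inverse()).as_matrix()
            assert np.abs(m - np.eye(4)).max() < 1e-9

    def test_composition_associative(self, rng):
        a, b, c = (random_rigid(rng) for _ in range(3))
        ab_c = AffineTransform3D(a.compose(b).as_matrix() @ c.as_matrix())
        a_bc = AffineTransform3D(a.as_matrix() @ b.compose(c).as_matrix())
        assert np.allclose(ab_c.matrix, a_bc.matrix, atol=1e-9)

    def test_matrix_round_trip(self, rng):
        t = random_rigid(rng, center=(1.0, 2.0, 3.0))
        back = rigid_from_matrix(t.as_matrix(), center=(1.0, 2.0, 3.0))
        assert np.allclose(back.as_matrix(), t.as_matrix(), atol=1e-9)


class TestAffineTransform:
    def test_requires_homogeneous_last_row(self):
        m = np.eye(4)
        m[3, 0] = 0.5
        with pytest.raises(InvalidTransformError):
            AffineTransform3D(m)

    def test_inverse(self, rng):
        m = np.eye(4)
        m[:3, :3] = np.eye(3) + rng.uniform(-0.2, 0.2, (3, 3))
        m[:3, 3] = rng.uniform(-5, 5, 3)
        t = AffineTransform3D(m)
        assert np.allclose(t.inverse().matrix @ m, np.eye(4), atol=1e-9)


class TestResample:
    def test_identity_reproduces_input(self):
        vol = make_volume()
        for interp, tol in (("nearest", 0.0), ("linear", 1e-12)):
            out = resample(vol, None, vol, interpolation=interp)
            assert np.abs(out.voxels - vol.voxels).max() <= tol

    def test_integer_voxel_shift_nearest_exact(self):
        vol = make_volume(spacing=(1, 1, 1), origin=(0, 0, 0))
        shift = RigidTransform3D(translation=(2.0, 0.0, 0.0))
        out = resample(vol, shift, vol, interpolation="nearest")
        assert np.array_equal(out.voxels[:6], vol.voxels[2:])

    def test_translate_there_and_back_small_error(self, phantom48):
        """Double linear interpolation loses little on a smooth image."""
        from scipy.ndimage import gaussian_filter
        smooth = phantom48.copy_geometry(gaussian_filter(phantom48.voxels, 4.0))
        t = (1.3, -0.7, 2.1)
        fwd = resample(smooth, RigidTransform3D(translation=t), smooth)
        back = resample(fwd, RigidTransform3D(translation=tuple(-x for x in t)), smooth)
        interior = (slice(6, -6),) * 3
        rng_span = smooth.voxels.max() - smooth.voxels.min()
        err = np.abs(back.voxels[interior] - smooth.voxels[interior]).max()
        assert err < 0.01 * rng_span

    def test_constant_volume_invariant_in_field(self, rng):
        vol = make_volume()
        vol.voxels[:] = 42.0
        t = random_rigid(rng, max_rot=30, max_trans=3)
        out, mask = resample(vol, t, vol, return_mask=True)
        assert np.allclose(out.voxels[mask], 42.0)
        assert np.all(out.voxels[~mask] == 0.0)

    def test_singular_transform_rejected(self):
        vol = make_volume()
        m = np.eye(4)
        m[0, 0] = 0.0
        with pytest.raises(InvalidTransformError):
            resample(vol, AffineTransform3D(m), vol)


class TestNiftiRoundTrip:
    def test_geometry_preserved(self, tmp_path):
        vol = make_volume()
        path = tmp_path / "vol.nii.gz"
        vol.to_nifti(path)
        back = ImageVolume.from_nifti(path)
        assert np.allclose(back.spacing, vol.spacing)
        assert np.allclose(back.origin, vol.origin)
        assert np.allclose(back.direction, vol.direction)
        assert np.allclose(back.voxels, vol.voxels, atol=1e-3)

    def test_transform_file_round_trip(self, tmp_path, rng):
        t = random_rigid(rng)
        path = tmp_path / "t.txt"
        save_transform(path, t)
        assert np.allclose(load_transform(path).matrix, t.as_matrix(), atol=1e-12)
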