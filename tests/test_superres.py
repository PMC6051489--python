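"""Forward simulation, SR objective, gradients and descent behaviour."""

import numpy as np
import pytest

from pvr import ImageVolume, PSFModel, RigidTransform3D, lambda_schedule, phi
from pvr.forward import build_footprint_entries, simulate_patch
from pvr.patches import Patch, extract_square_patches
from pvr.psf import discretize_psf
from pvr.superres import (
    SRState,
    build_bundle,
    data_gradient,
    data_term,
    initialize_volume,
    objective,
    regularizer_energy,
    regularizer_gradient,
    sr_step,
)

PSF = PSFModel((1.25, 1.25), 2.5)


def oracle_simulate(volume, patch, stack, footprint):
    """Independent triple-loop forward simulation (the reference)."""
    out = np.full(len(patch.pixels), np.nan)
    inv = np.linalg.inv(patch.transform.as_matrix())
    frame = patch.transform.rotation_matrix().T @ stack.direction
    for pi in range(len(patch.pixels)):
        i, j = patch.pixels[pi]
        world = stack.voxel_to_world([float(i), float(j), float(patch.slice_index)])
        recon = inv[:3, :3] @ world + inv[:3, 3]
        num = den = 0.0
        for off, w in zip(footprint.offsets, footprint.weights):
            idx = volume.world_to_voxel(recon + frame @ off)
            i0 = np.floor(idx).astype(int)
            f = idx - i0
            for di in (0, 1):
                for dj in (0, 1):
                    for dk in (0, 1):
                        ci = i0 + np.array([di, dj, dk])
                        if np.any(ci < 0) or np.any(ci >= np.array(volume.shape)):
                            continue
                        cw = ((f[0] if di else 1 - f[0])
                              * (f[1] if dj else 1 - f[1])
                              * (f[2] if dk else 1 - f[2]))
                        if cw <= 0:
                            continue
                        num += w * cw * volume.voxels[tuple(ci)]
                        den += w * cw
        if den > 0:
            out[pi] = num / den
    return out


def slice_patch(stack, k=4, a=8, transform=None):
    p = extract_square_patches(stack.voxels[:, :, k], a=a, stride=a, slice_index=k)[0]
    if transform is not None:
        p.transform = transform
    return p


class TestSimulatePatch:
    def test_constant_volume_gives_constant_patch(self, small_volume):
        const = small_volume.copy_geometry(np.full(small_volume.shape, 3.5))
        patch = slice_patch(small_volume)
        sim = simulate_patch(const, patch, small_volume, PSF)
        ok = np.isfinite(sim)
        assert ok.any()
        assert np.allclose(sim[ok], 3.5, atol=1e-12)

    def test_matches_triple_loop_oracle(self, small_volume):
        """Vectorized forward model equals the naive reference within 1e-9."""
        fp = discretize_psf(PSF, step=min(small_volume.spacing))
        transform = RigidTransform3D(rotation=(3.0, -2.0, 5.0),
                                     translation=(0.8, -0.4, 1.2),
                                     center=(5.0, 5.0, 10.0))
        patch = slice_patch(small_volume, transform=transform)
        sim = simulate_patch(small_volume, patch, small_volume, PSF, footprint=fp)
        ref = oracle_simulate(small_volume, patch, small_volume, fp)
        both = np.isfinite(sim) & np.isfinite(ref)
        assert np.array_equal(np.isfinite(sim), np.isfinite(ref))
        assert np.abs(sim[both] - ref[both]).max() < 1e-9

    def test_delta_psf_limit_is_interpolation(self, small_volume):
        """A vanishingly narrow PSF reduces simulation to volume interpolation."""
        narrow = PSFModel((0.05, 0.05), 0.05, support_radius=0.2)
        patch = slice_patch(small_volume)
        sim = simulate_patch(small_volume, patch, small_volume, narrow)
        expected = small_volume.voxels[patch.pixels[:, 0], patch.pixels[:, 1], 4]
        ok = np.isfinite(sim)
        assert np.allclose(sim[ok], expected[ok], atol=1e-9)


class TestPhiAndLambda:
    def test_phi_closed_form_values(self):
        assert phi(0.0) == 0.0
        assert np.isclose(phi(1.0), 2 * np.sqrt(2) - 2)
        assert np.isclose(phi(1e6) / 1e6, 2.0, atol=1e-5)
        t = np.linspace(-5, 5, 101)
        assert np.allclose(phi(t), phi(-t))

    def test_lambda_schedule_halves(self):
        assert lambda_schedule(150.0, 0) == 0.8 * 150.0 ** 2
        assert lambda_schedule(150.0, 1) == 0.5 * lambda_schedule(150.0, 0)
        lams = [lambda_schedule(150.0, k) for k in range(10)]
        assert np.all(np.diff(lams) < 0)


@pytest.fixture()
def small_problem(small_volume):
    patches = []
    for k in (2, 7, 12):
        patches.append(slice_patch(small_volume, k=k, a=16))
    bundle = build_bundle(patches, [small_volume], small_volume, PSF)
    return patches, bundle


class TestGradients:
    def test_data_gradient_matches_finite_differences(self, small_volume, small_problem,
                                                      rng):
        _, bundle = small_problem
        vol = small_volume.copy_geometry(small_volume.voxels + rng.normal(0, 5, small_volume.shape))
        g = data_gradient(bundle, vol)
        h = 1e-3
        for _ in range(20):
            i, j, k = rng.integers(0, np.array(small_volume.shape))
            if abs(g[i, j, k]) < 1e-8:
                continue
            plus = vol.copy_geometry(vol.voxels.copy())
            plus.voxels[i, j, k] += h
            minus = vol.copy_geometry(vol.voxels.copy())
            minus.voxels[i, j, k] -= h
            fd = (data_term(bundle, plus) - data_term(bundle, minus)) / (2 * h)
            assert abs(fd - g[i, j, k]) / max(abs(fd), 1e-12) < 1e-4

    def test_regularizer_gradient_matches_finite_differences(self, small_volume, rng):
        vox = small_volume.voxels
        g = regularizer_gradient(vox, delta=50.0)
        h = 1e-4
        for _ in range(10):
            i, j, k = rng.integers(0, np.array(vox.shape))
            p, m = vox.copy(), vox.copy()
            p[i, j, k] += h
            m[i, j, k] -= h
            fd = (regularizer_energy(p, 50.0) - regularizer_energy(m, 50.0)) / (2 * h)
            assert abs(fd - g[i, j, k]) / max(abs(fd), 1e-8) < 1e-4


class TestSRDescent:
    def test_objective_decreases_over_accepted_steps(self, small_volume, small_problem):
        _, bundle = small_problem
        state = initialize_volume(bundle, small_volume)
        state.delta = 150.0
        from pvr.superres import lambda_schedule
        for _ in range(10):
            lam = lambda_schedule(state.delta, state.iteration)  # what the step uses
            before = objective(bundle, state.volume, lam, state.delta)
            state = sr_step(state, bundle)
            assert not state.last_step_rejected
            after = objective(bundle, state.volume, lam, state.delta)
            assert after < before

    def test_consensus_constant_is_fixed_point(self, small_volume):
        patches = [slice_patch(small_volume, k=k, a=16) for k in (3, 8, 13)]
        for p in patches:
            p.values = np.full(p.n_pixels, 11.0)
        bundle = build_bundle(patches, [small_volume], small_volume, PSF)
        state = initialize_volume(bundle, small_volume)
        covered = state.confidence > 0
        assert np.allclose(state.volume.voxels[covered.reshape(state.volume.shape)],
                           11.0, atol=1e-9)
        assert data_term(bundle, state.volume) < 1e-12

    def test_zero_posterior_removes_patch_influence(self, small_volume, rng):
        """A patch with p-hat = 0 leaves the reconstruction bit-identical."""
        def run(values_for_last):
            patches = [slice_patch(small_volume, k=k, a=16) for k in (3, 8)]
            extra = slice_patch(small_volume, k=12, a=16)
            extra.values = values_for_last
            extra.included = False
            extra.patch_posterior = 0.0
            patches.append(extra)
            bundle = build_bundle(patches, [small_volume], small_volume, PSF)
            bundle.set_posteriors(patches)
            state = initialize_volume(bundle, small_volume)
            state.confidence = bundle.scatter(bundle.pw)
            for _ in range(3):
                state = sr_step(state, bundle)
            return state.volume.voxels

    # same seed-independent inputs, two different excluded-patch contents
        a = run(np.full(256, 500.0))
        b = run(rng.random(256) * 1000)
        assert np.array_equal(a, b)

    def test_pure_regularizer_flattens(self, small_volume):
        patches = [slice_patch(small_volume, k=8, a=16)]
        bundle = build_bundle(patches, [small_volume], small_volume, PSF)
        bundle.pw[:] = 0.0  # no data
        state = SRState(volume=small_volume.copy_geometry(),
                        confidence=np.zeros(small_volume.shape),
                        delta=150.0, lambda0_factor=None, lam=1e4)
        spread0 = state.volume.voxels.std()
        for _ in range(20):
            state = sr_step(state, bundle, step0=1.0)
            if state.last_step_rejected:
                break
        assert state.volume.voxels.std() < spread0
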