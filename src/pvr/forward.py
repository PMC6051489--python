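"""PSF-based forward model linking acquired patches to the HR volume.

Each acquired pixel observes a convex combination of HR voxels: the PSF is
discretized on a slice-frame lattice (see :func:`pvr.psf.discretize_psf`),
each lattice sample is mapped through the patch's rigid pose into the
reconstruction space and assigned to its nearest HR voxel, and the
surviving (in-field) weights are normalized per pixel to sum to one.

The same sparse pixel->voxel weight table drives simulation (gather),
super-resolution (scatter of residuals, the exact transpose) and the
rigidity map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ImageVolume
from .patches import Patch
from .psf import PSFFootprint, PSFModel, discretize_psf


def patch_pixel_world(patch: Patch, stack: ImageVolume) -> np.ndarray:
    """World (acquisition-space) mm coordinates of the patch's pixel centres."""
    n = len(patch.pixels)
    idx = np.column_stack([patch.pixels, np.full(n, patch.slice_index)])
    return stack.voxel_to_world(idx)


def slice_frame_in_recon(patch: Patch, stack: ImageVolume) -> np.ndarray:
    """Slice coordinate axes expressed in reconstruction space.

    Columns: in-plane axis 0, in-plane axis 1, slice normal.  The patch
    transform maps reconstruction space into acquisition space (pull), so
    the frame is rotated by its inverse rotation.
    """
    return patch.transform.rotation_matrix().T @ stack.direction


@dataclass
class FootprintEntries:
    """Sparse pixel->voxel weight table for one patch.

    ``pixel_id`` indexes the patch's pixels, ``voxel_flat`` raveled HR
    voxel indices, ``weight`` the per-entry normalized PSF weight (rows of
    one pixel sum to 1).  ``valid`` flags pixels with any in-field weight.
    """

    pixel_id: np.ndarray
    voxel_flat: np.ndarray
    weight: np.ndarray
    valid: np.ndarray
    n_pixels: int


def default_footprint(psf: PSFModel, volume: ImageVolume) -> PSFFootprint:
    """Footprint lattice at the HR voxel spacing (one sample per voxel)."""
    return discretize_psf(psf, step=min(volume.spacing))


def build_footprint_entries(volume: ImageVolume, patch: Patch, stack: ImageVolume,
                            footprint: PSFFootprint) -> FootprintEntries:
    """Discretized PSF support of every patch pixel in the HR grid.

    Each slice-frame PSF lattice sample is spread trilinearly over its 8
    surrounding HR voxels, so sub-voxel sample positions are represented
    exactly instead of being rounded to the nearest voxel.
    """
    pix_world = patch_pixel_world(patch, stack)            # acquisition space
    inv = patch.transform.inverse()
    pix_recon = inv.apply(pix_world)                        # reconstruction space
    frame = slice_frame_in_recon(patch, stack)
    samples = pix_recon[:, None, :] + (footprint.offsets @ frame.T)[None, :, :]
    n, m = samples.shape[:2]
    idx = volume.world_to_voxel(samples.reshape(-1, 3))
    i0 = np.floor(idx).astype(np.int64)
    frac = idx - i0
    shape = np.asarray(volume.shape)
    base_w = np.tile(footprint.weights, n)
    sample_pix = np.repeat(np.arange(n, dtype=np.int64), m)
    pix_parts, vox_parts, w_parts = [], [], []
    for corner in range(8):
        d = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        ci = i0 + d[None, :]
        cw = np.prod(np.where(d[None, :] == 1, frac, 1.0 - frac), axis=1)
        keep = (cw > 0) & np.all((ci >= 0) & (ci < shape[None, :]), axis=1)
        if not keep.any():
            continue
        pix_parts.append(sample_pix[keep])
        vox_parts.append(np.ravel_multi_index(tuple(ci[keep].T), volume.shape))
        w_parts.append(base_w[keep] * cw[keep])
    if pix_parts:
        pixel_id = np.concatenate(pix_parts)
        vox_flat = np.concatenate(vox_parts)
        w = np.concatenate(w_parts)
        # merge duplicate (pixel, voxel) pairs — adjacent lattice samples
        # often share trilinear corners, so this shrinks the table a lot
        nvox = int(np.prod(volume.shape))
        key = pixel_id * nvox + vox_flat
        uniq, inv = np.unique(key, return_inverse=True)
        w = np.bincount(inv, weights=w)
        pixel_id = (uniq // nvox).astype(np.int32)
        vox_flat = (uniq % nvox).astype(np.int32)
    else:  # patch fully outside the volume
        pixel_id = np.empty(0, dtype=np.int32)
        vox_flat = np.empty(0, dtype=np.int32)
        w = np.empty(0)
    wsum = np.bincount(pixel_id, weights=w, minlength=n)
    valid = wsum > 0
    if len(w):
        w = w / wsum[pixel_id]
    return FootprintEntries(pixel_id, vox_flat, w, valid, n)


def simulate_from_entries(volume: ImageVolume, entries: FootprintEntries) -> np.ndarray:
    """Simulated patch intensities y* (NaN where the pixel saw no voxel)."""
    acc = np.bincount(entries.pixel_id,
                      weights=entries.weight * volume.voxels.ravel()[entries.voxel_flat],
                      minlength=entries.n_pixels)
    acc[~entries.valid] = np.nan
    return acc


def simulate_patch(volume: ImageVolume, patch: Patch, stack: ImageVolume,
                   psf: PSFModel, footprint: PSFFootprint | None = None) -> np.ndarray:
    """Simulate the acquired patch from the HR volume through the PSF.

    Returns one value per patch pixel; pixels whose footprint lies fully
    outside the volume are NaN.
    """
    if footprint is None:
        footprint = default_footprint(psf, volume)
    entries = build_footprint_entries(volume, patch, stack, footprint)
    return simulate_from_entries(volume, entries)


def scatter_to_volume(values: np.ndarray, entries: FootprintEntries,
                      volume_shape, out: np.ndarray | None = None) -> np.ndarray:
    """Transpose of simulation: spread per-pixel values into the HR grid."""
    if out is None:
        out = np.zeros(int(np.prod(volume_shape)))
    vals = np.where(entries.valid[entries.pixel_id], values[entries.pixel_id], 0.0)
    out += np.bincount(entries.voxel_flat, weights=entries.weight * vals,
                       minlength=out.size)
    return out


def trilinear_sample(voxels: np.ndarray, idx: np.ndarray):
    """Fast trilinear interpolation at continuous voxel indices.

    Returns ``(values, in_field)``; out-of-field values are 0.
    """
    shape = np.asarray(voxels.shape)
    in_field = np.all((idx >= 0) & (idx <= (shape - 1)[None, :]), axis=1)
    p = np.clip(idx, 0, (shape - 1.0000001)[None, :])
    i0 = np.floor(p).astype(np.int64)
    f = p - i0
    x0, y0, z0 = i0.T
    fx, fy, fz = f.T
    v = voxels
    c00 = v[x0, y0, z0] * (1 - fx) + v[x0 + 1, y0, z0] * fx
    c10 = v[x0, y0 + 1, z0] * (1 - fx) + v[x0 + 1, y0 + 1, z0] * fx
    c01 = v[x0, y0, z0 + 1] * (1 - fx) + v[x0 + 1, y0, z0 + 1] * fx
    c11 = v[x0, y0 + 1, z0 + 1] * (1 - fx) + v[x0 + 1, y0 + 1, z0 + 1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    out = c0 * (1 - fz) + c1 * fz
    out[~in_field] = 0.0
    return out, in_field
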