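"""Decomposition of acquired 2D slices into overlapping patches.

Two patch shapes are supported: square patches on a stride lattice, and
SLIC superpixels seeded on a regular grid of spacing ``a`` and then
morphologically dilated by ``gamma`` pixels so neighbouring patches
overlap.  The superpixel clustering itself is delegated to
scikit-image's SLIC, which minimizes the joint spatial/intensity distance

    D = sqrt(d_c^2 + (d_s / a)^2 t^2)

with compactness ``t``.  A multi-scale schedule grows the nominal patch
size by a constant factor between reconstruction passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import morphology
from skimage.segmentation import slic

from .geometry import ImageVolume, InvalidParameterError, RigidTransform3D


@dataclass
class Patch:
    """A 2D pixel region within one acquired slice.

    ``pixels`` are (N, 2) in-slice integer coordinates, ``values`` the
    intensities at those pixels.  The rigid ``transform`` (pull
    convention: reconstruction space -> acquisition space) starts from the
    parent stack's transform and is refined by patch-to-volume
    registration.  ``posterior_map`` holds the per-pixel inlier
    probability p, ``patch_posterior`` the aggregate p-hat.
    """

    stack_id: int
    slice_index: int
    pixels: np.ndarray
    values: np.ndarray
    transform: RigidTransform3D = field(default_factory=RigidTransform3D)
    scale_index: int = 0
    posterior_map: np.ndarray | None = None
    patch_posterior: float = 1.0
    included: bool = True
    registerable: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2 or len(self.pixels) == 0:
            raise InvalidParameterError("patch must have a non-empty (N, 2) pixel set")
        if len(self.values) != len(self.pixels):
            raise InvalidParameterError("values and pixels must align")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("patch intensities must be finite")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    def centroid(self) -> np.ndarray:
        return self.pixels.mean(axis=0)


@dataclass
class SuperpixelParams:
    """SLIC settings: grid step ``a``, compactness ``t``, dilation ``gamma``."""

    a: int = 16
    compactness: float = 0.1
    gamma: float = 60.0
    gamma_units: str = "percent"  # "percent" of a, or "px"
    iterations: int = 10

    def __post_init__(self) -> None:
        if self.a < 4:
            raise InvalidParameterError("superpixel grid step a must be >= 4")
        if self.compactness <= 0:
            raise InvalidParameterError("compactness must be positive")
        if self.gamma < 0:
            raise InvalidParameterError("gamma must be >= 0")
        if self.gamma_units not in ("px", "percent"):
            raise InvalidParameterError("gamma_units must be 'px' or 'percent'")

    def gamma_pixels(self) -> int:
        if self.gamma_units == "px":
            return int(round(self.gamma))
        return int(round(self.gamma / 100.0 * self.a))


def _lattice_positions(extent: int, stride: int) -> np.ndarray:
    return np.arange(0, extent, stride, dtype=int)


def extract_square_patches(slice2d: np.ndarray, a: int, stride: int,
                           stack_id: int = 0, slice_index: int = 0,
                           transform: RigidTransform3D | None = None,
                           scale_index: int = 0) -> list[Patch]:
    """Square patches of edge ``a`` on a stride lattice, cropped at borders.

    With stride < a the patches overlap; with stride == a they tile the
    slice exactly.  Every pixel is covered by at least one patch.
    """
    slice2d = np.asarray(slice2d, dtype=np.float64)
    if a < 4:
        raise InvalidParameterError("patch edge a must be >= 4")
    if stride < 1 or stride > a:
        raise InvalidParameterError("stride must satisfy 1 <= stride <= a")
    h, w = slice2d.shape
    patches = []
    for i0 in _lattice_positions(h, stride):
        for j0 in _lattice_positions(w, stride):
            i1, j1 = min(i0 + a, h), min(j0 + a, w)
            ii, jj = np.mgrid[i0:i1, j0:j1]
            pix = np.column_stack([ii.ravel(), jj.ravel()])
            patches.append(Patch(
                stack_id=stack_id, slice_index=slice_index, pixels=pix,
                values=slice2d[pix[:, 0], pix[:, 1]],
                transform=transform if transform is not None else RigidTransform3D(),
                scale_index=scale_index))
    return patches


def extract_superpixels(slice2d: np.ndarray, params: SuperpixelParams) -> np.ndarray:
    """SLIC label map (a partition of the slice), seeds on an ``a`` grid."""
    slice2d = np.asarray(slice2d, dtype=np.float64)
    if not np.all(np.isfinite(slice2d)):
        raise InvalidParameterError("slice intensities must be finite")
    h, w = slice2d.shape
    if h <= params.a or w <= params.a:
        raise InvalidParameterError("image must be larger than the grid step a")
    n_segments = max(1, round(h / params.a) * round(w / params.a))
    labels = slic(
        slice2d,
        n_segments=n_segments,
        compactness=params.compactness,
        max_num_iter=params.iterations,
        channel_axis=None,
        enforce_connectivity=True,
        start_label=0,
    )
    return labels


def dilate_superpixels(labels: np.ndarray, gamma: int, slice2d: np.ndarray | None = None,
                       stack_id: int = 0, slice_index: int = 0,
                       transform: RigidTransform3D | None = None,
                       scale_index: int = 0) -> list[Patch]:
    """Turn a label partition into overlapping patches by dilation.

    Each label's mask is dilated by a flat disk of radius ``gamma``
    pixels; gamma = 0 returns the partition unchanged.  ``slice2d``
    supplies intensities (zeros if omitted, useful for mask-only tests).
    """
    labels = np.asarray(labels)
    if gamma < 0:
        raise InvalidParameterError("gamma must be >= 0")
    if slice2d is None:
        slice2d = np.zeros(labels.shape)
    slice2d = np.asarray(slice2d, dtype=np.float64)
    selem = morphology.disk(gamma) if gamma > 0 else None
    patches = []
    for lab in np.unique(labels):
        mask = labels == lab
        if selem is not None:
            mask = morphology.dilation(mask, footprint=selem)
        pix = np.column_stack(np.nonzero(mask))
        patches.append(Patch(
            stack_id=stack_id, slice_index=slice_index, pixels=pix,
            values=slice2d[pix[:, 0], pix[:, 1]],
            transform=transform if transform is not None else RigidTransform3D(),
            scale_index=scale_index))
    return patches


def multiscale_schedule(a0: int, factor: float, n_scales: int,
                        iterations_per_scale: int = 2) -> list[tuple[int, int, int]]:
    """Per-scale patch sizes: ``a_i = round(a0 * factor**i)``.

    Returns ``(scale_index, a_i, iterations)`` triples; factor = 1 yields
    the fixed-scale variant.
    """
    if a0 < 4:
        raise InvalidParameterError("a0 must be >= 4")
    if factor < 1:
        raise InvalidParameterError("factor must be >= 1")
    if n_scales < 1 or iterations_per_scale < 1:
        raise InvalidParameterError("n_scales and iterations_per_scale must be >= 1")
    return [(i, int(round(a0 * factor ** i)), iterations_per_scale)
            for i in range(n_scales)]


def coverage_count(patches: list[Patch], shape: tuple[int, int]) -> np.ndarray:
    """How many patches cover each pixel of a slice."""
    count = np.zeros(shape, dtype=int)
    for p in patches:
        count[p.pixels[:, 0], p.pixels[:, 1]] += 1
    return count
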