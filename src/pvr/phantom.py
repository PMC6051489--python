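"""Procedural 3D phantom and synthetic motion corruption.

The phantom is a nested-ellipsoid "head": background, a bright shell, a
mid-intensity tissue compartment with smooth random texture, dark
ventricle-like cavities and a bright deep nucleus.  It is piecewise smooth
with sharp class boundaries, giving registration and super-resolution
features to lock onto, and is fully deterministic given a seed.

Synthetic corruption reproduces three classic motion experiments on such a
phantom: whole-volume rigid translation, bulk rotation of the upper half
about the z axis (the lower half stays untouched), and a global skew whose
six off-diagonal shear entries all equal tan(theta).  Motion-corrupted
stacks are then sampled slice-interleaved from the motion-free and the
corrupted volume at anisotropic spacing, emulating motion that happens
between interleaved 2D slice acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import (
    AffineTransform3D,
    ImageVolume,
    InvalidParameterError,
    RigidTransform3D,
    resample,
)

INTENSITY_RANGE = (0.0, 1000.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

_TISSUE = 500.0
_SHELL = 850.0
_NUCLEUS = 700.0
_VENTRICLE = 150.0
_TEXTURE_AMPLITUDE = 45.0


def make_phantom(size=(96, 96, 96), spacing=(1.0, 1.0, 1.0), seed: int = 0) -> ImageVolume:
    """Deterministic nested-ellipsoid phantom with textured tissue.

    ``size`` must be at least 32 voxels per axis.  Intensities lie in
    ``INTENSITY_RANGE`` with at least three well-separated histogram modes
    (background, tissue, shell).
    """
    size = tuple(int(s) for s in np.broadcast_to(size, (3,)))
    if min(size) < 32:
        raise InvalidParameterError("phantom size must be >= 32 voxels per axis")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=np.float64), (3,)).copy()
    rng = np.random.default_rng(seed)

    # normalized coordinates in [-1, 1] per axis
    grids = [np.linspace(-1.0, 1.0, n) for n in size]
    x, y, z = np.meshgrid(*grids, indexing="ij")

    def ellipsoid(cx, cy, cz, ax, ay, az):
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    outer = ellipsoid(0, 0, 0, 0.92, 0.88, 0.85)
    inner = ellipsoid(0, 0, 0, 0.80, 0.76, 0.73)
    shell = outer & ~inner

    vox = np.zeros(size)
    vox[shell] = _SHELL
    vox[inner] = _TISSUE

    nucleus = ellipsoid(0.0, 0.05, -0.05, 0.28, 0.22, 0.25)
    vox[nucleus & inner] = _NUCLEUS
    for sx in (-1.0, 1.0):
        vent = ellipsoid(0.28 * sx, -0.12, 0.18, 0.14, 0.22, 0.3)
        vox[vent & inner] = _VENTRICLE
    # a few off-centre blobs for rotational asymmetry
    for cx, cy, cz, r, val in ((0.45, 0.3, -0.3, 0.1, 800.0),
                               (-0.4, 0.35, 0.25, 0.12, 300.0),
                               (0.1, -0.45, -0.2, 0.09, 650.0)):
        blob = ellipsoid(cx, cy, cz, r, r, r)
        vox[blob & inner] = val

    texture = ndimage.gaussian_filter(rng.standard_normal(size), sigma=2.0)
    texture *= _TEXTURE_AMPLITUDE / max(texture.std(), 1e-12)
    vox[inner] += texture[inner]

    np.clip(vox, *INTENSITY_RANGE, out=vox)
    return ImageVolume(vox, spacing, origin=np.zeros(3))


@dataclass
class MotionSpec:
    """Description of one synthetic deformation.

    Exactly one of the three kinds is active: ``rigid_translation`` shifts
    the whole volume by ``d_x`` mm along x; ``bulk_rotation`` rotates only
    the upper half (along z) by ``theta_z`` degrees about the z axis;
    ``skew`` applies an affine whose six off-diagonal shear entries all
    equal ``tan(theta_xyz)``, about the volume centre.
    """

    kind: str
    d_x: float = 0.0
    theta_z: float = 0.0
    theta_xyz: float = 0.0

    _KINDS = ("rigid_translation", "bulk_rotation", "skew")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidParameterError(f"kind must be one of {self._KINDS}")
        if self.kind == "skew" and abs(self.theta_xyz) >= 45.0:
            raise InvalidParameterError("skew angle must satisfy |theta| < 45 degrees")

    def shear_value(self) -> float:
        return float(np.tan(np.deg2rad(self.theta_xyz)))

    def skew_matrix(self, center) -> AffineTransform3D:
        s = self.shear_value()
        lin = np.array([[1.0, s, s], [s, 1.0, s], [s, s, 1.0]])
        m = np.eye(4)
        m[:3, :3] = lin
        c = np.asarray(center, dtype=np.float64)
        m[:3, 3] = c - lin @ c
        return AffineTransform3D(m)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "d_x": self.d_x, "theta_z": self.theta_z,
                "theta_xyz": self.theta_xyz}


def _volume_center(volume: ImageVolume) -> np.ndarray:
    lo, hi = volume.world_bounds()
    return (lo + hi) / 2.0


def apply_motion(volume: ImageVolume, spec: MotionSpec,
                 interpolation: str = "linear") -> ImageVolume:
    """Return a motion-corrupted copy of ``volume`` on the same grid."""
    if spec.kind == "rigid_translation":
        # pull transform: sample the source at x + d moves content by -d;
        # here content moves by +d_x along world x
        t = RigidTransform3D(translation=(-spec.d_x, 0.0, 0.0))
        return resample(volume, t, volume, interpolation=interpolation)
    if spec.kind == "skew":
        tf = spec.skew_matrix(_volume_center(volume)).inverse()
        return resample(volume, tf, volume, interpolation=interpolation)
    # bulk rotation: upper half (large k along axis 2) rotated, lower half
    # copied verbatim; the boundary mid-plane slice belongs to the moved half
    center = _volume_center(volume)
    pull = RigidTransform3D(rotation=(0.0, 0.0, -spec.theta_z), center=center)
    rotated = resample(volume, pull, volume, interpolation=interpolation)
    out = volume.copy_geometry()
    k_split = volume.shape[2] // 2
    out.voxels[:, :, k_split:] = rotated.voxels[:, :, k_split:]
    return out


_ORIENT_AXES = {
    # stack index axes (in-plane 0, in-plane 1, slice axis) as world axes
    "axial": (0, 1, 2),
    "coronal": (0, 2, 1),
    "sagittal": (1, 2, 0),
}


@dataclass
class StackSpec:
    """Geometry of one synthetically acquired stack."""

    orientation: str = "axial"
    in_plane_spacing: float = 1.25
    slice_thickness: float = 2.5
    interleave_pattern: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.orientation not in _ORIENT_AXES:
            raise InvalidParameterError(f"orientation must be one of {tuple(_ORIENT_AXES)}")
        if self.in_plane_spacing <= 0 or self.slice_thickness <= 0:
            raise InvalidParameterError("spacings must be positive")


def stack_geometry(volume: ImageVolume, spec: StackSpec) -> ImageVolume:
    """Empty stack grid covering ``volume``'s field of view."""
    lo, hi = volume.world_bounds()
    axes = _ORIENT_AXES[spec.orientation]
    spacing = np.array([spec.in_plane_spacing, spec.in_plane_spacing, spec.slice_thickness])
    extent = (hi - lo)[list(axes)]
    n = np.maximum(np.floor(extent / spacing).astype(int) + 1, 1)
    direction = np.zeros((3, 3))
    for stack_ax, world_ax in enumerate(axes):
        direction[world_ax, stack_ax] = 1.0
    origin = lo.copy()
    return ImageVolume(np.zeros(tuple(n)), spacing, origin, direction)


def sample_interleaved_stack(free: ImageVolume, corrupted: ImageVolume,
                             spec: StackSpec) -> ImageVolume:
    """Sample a stack whose slices alternate between two motion states.

    Even slice indices come from ``free``, odd from ``corrupted``, unless
    ``spec.interleave_pattern`` (a per-slice sequence over {"free",
    "corrupted"}) says otherwise.
    """
    if free.shape != corrupted.shape or not np.allclose(free.spacing, corrupted.spacing) \
            or not np.allclose(free.origin, corrupted.origin) \
            or not np.allclose(free.direction, corrupted.direction):
        raise InvalidParameterError("free and corrupted volumes must share geometry")
    grid = stack_geometry(free, spec)
    n_slices = grid.shape[2]
    pattern = spec.interleave_pattern
    if pattern is None:
        pattern = ["free" if k % 2 == 0 else "corrupted" for k in range(n_slices)]
    if len(pattern) != n_slices:
        raise InvalidParameterError(
            f"interleave pattern length {len(pattern)} != slice count {n_slices}")

    # thick-slice excitation: integrate a Gaussian slice profile (FWHM =
    # slice thickness) along the slice axis before sampling
    slice_axis_world = _ORIENT_AXES[spec.orientation][2]
    sigma_vox = spec.slice_thickness * _FWHM_TO_SIGMA / free.spacing[slice_axis_world]
    sigma = [0.0, 0.0, 0.0]
    sigma[slice_axis_world] = sigma_vox
    free_blurred = free.copy_geometry(ndimage.gaussian_filter(free.voxels, sigma=sigma))
    corr_blurred = corrupted.copy_geometry(ndimage.gaussian_filter(corrupted.voxels, sigma=sigma))
    res_free = resample(free_blurred, None, grid, interpolation="linear")
    res_corr = resample(corr_blurred, None, grid, interpolation="linear")
    out = grid.copy_geometry()
    for k, state in enumerate(pattern):
        if state not in ("free", "corrupted"):
            raise InvalidParameterError(f"bad interleave state {state!r}")
        src = res_free if state == "free" else res_corr
        out.voxels[:, :, k] = src.voxels[:, :, k]
    return out


def make_motion_experiment(spec: MotionSpec, size=(96, 96, 96), seed: int = 0,
                           orientations=("axial", "sagittal", "coronal"),
                           in_plane_spacing: float = 1.25,
                           slice_thickness: float = 2.5):
    """Phantom + interleaved corrupted stacks for one motion experiment.

    Returns ``(phantom, corrupted_volume, stacks)`` where ``stacks`` is one
    interleaved anisotropic stack per requested orientation.
    """
    phantom = make_phantom(size=size, seed=seed)
    corrupted = apply_motion(phantom, spec)
    stacks = [
        sample_interleaved_stack(
            phantom, corrupted,
            StackSpec(orientation=o, in_plane_spacing=in_plane_spacing,
                      slice_thickness=slice_thickness))
        for o in orientations
    ]
    return phantom, corrupted, stacks
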