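"""Physical-space image model and rigid/affine transforms.

Images are 3D scalar grids with anisotropic spacing, a world origin and an
orthonormal direction matrix (voxel-center convention, 0-based indices):

    world = origin + direction @ (spacing * index)

All transforms in this package follow the *pull* (resampling) convention:
a transform handed to :func:`resample` maps points of the fixed/target
space into the moving image's space.  The forward motion of an acquired
slice or stack is therefore the inverse of the transform stored for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation


class InvalidTransformError(ValueError):
    """Raised when a transform is singular or otherwise unusable."""


class InvalidParameterError(ValueError):
    """Raised when a parameter violates its documented domain."""


@dataclass
class ImageVolume:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    voxels:
        3D array of intensities, indexed ``[i, j, k]``.
    spacing:
        Millimetres per voxel along each index axis; all positive.
    origin:
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    direction:
        3x3 orthonormal matrix whose columns are the world directions of
        the index axes.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.direction = np.asarray(self.direction, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise InvalidParameterError("voxels must be a 3D array")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise InvalidParameterError("spacing must be 3 positive reals")
        if not np.allclose(self.direction @ self.direction.T, np.eye(3), atol=1e-9):
            raise InvalidParameterError("direction matrix must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    # ---- index <-> world maps -------------------------------------------
    def index_to_world_matrix(self) -> np.ndarray:
        """4x4 affine taking continuous voxel indices to world mm."""
        m = np.eye(4)
        m[:3, :3] = self.direction * self.spacing[None, :]
        m[:3, 3] = self.origin
        return m

    def voxel_to_world(self, index) -> np.ndarray:
        index = np.asarray(index, dtype=np.float64)
        return (self.direction @ (self.spacing * index).T).T + self.origin

    def world_to_voxel(self, point) -> np.ndarray:
        point = np.asarray(point, dtype=np.float64)
        return (self.direction.T @ (point - self.origin).T).T / self.spacing

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box of all voxel centres."""
        n = np.array(self.shape) - 1
        corners = np.array(
            [[i, j, k] for i in (0, n[0]) for j in (0, n[1]) for k in (0, n[2])],
            dtype=np.float64,
        )
        w = self.voxel_to_world(corners)
        return w.min(axis=0), w.max(axis=0)

    def copy_geometry(self, voxels: np.ndarray | None = None) -> "ImageVolume":
        vox = self.voxels.copy() if voxels is None else np.asarray(voxels, float)
        return ImageVolume(vox, self.spacing.copy(), self.origin.copy(), self.direction.copy())

    # ---- I/O -------------------------------------------------------------
    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.voxels, dtype=np.float32), self.index_to_world_matrix())
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        affine = np.asarray(img.affine, dtype=np.float64)
        lin = affine[:3, :3]
        spacing = np.linalg.norm(lin, axis=0)
        direction = lin / spacing[None, :]
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), spacing, affine[:3, 3], direction)


@dataclass
class RigidTransform3D:
    """6-parameter rigid transform: ``p' = R (p - c) + c + t``.

    Rotation is given as extrinsic x-y-z Euler angles in degrees
    (applied as ``Rz @ Ry @ Rx``), translation in mm, about centre ``c``.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        self.center = np.asarray(self.center, dtype=np.float64)

    def rotation_matrix(self) -> np.ndarray:
        # explicit extrinsic x-y-z product (== Rz @ Ry @ Rx); equivalent to
        # scipy's Rotation.from_euler("xyz", ..., degrees=True) but ~4x faster
        ax, ay, az = np.deg2rad(self.rotation)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        return np.array([
            [cz * cy, cz * sy * sx - sz * cx, cz * sy * cx + sz * sx],
            [sz * cy, sz * sy * sx + cz * cx, sz * sy * cx - cz * sx],
            [-sy, cy * sx, cy * cx],
        ])

    def as_matrix(self) -> np.ndarray:
        r = self.rotation_matrix()
        m = np.eye(4)
        m[:3, :3] = r
        m[:3, 3] = self.center + self.translation - r @ self.center
        return m

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        r = self.rotation_matrix()
        return (r @ (points - self.center).T).T + self.center + self.translation

    def inverse(self) -> "RigidTransform3D":
        r = self.rotation_matrix().T
        angles = Rotation.from_matrix(r).as_euler("xyz", degrees=True)
        # p = R^T (p' - c - t) + c  ==  R^T (p' - c) + c + t_inv
        t_inv = r @ (-self.translation)
        return RigidTransform3D(angles, t_inv, self.center.copy())

    def compose(self, other: "RigidTransform3D") -> "AffineTransform3D":
        """Transform applying ``other`` first, then ``self``."""
        return AffineTransform3D(self.as_matrix() @ other.as_matrix())

    def parameters(self) -> np.ndarray:
        return np.concatenate([self.rotation, self.translation])


@dataclass
class AffineTransform3D:
    """Homogeneous 4x4 affine transform in world (mm) space."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise InvalidParameterError("matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1], atol=1e-12):
            raise InvalidTransformError("last row must be (0, 0, 0, 1)")

    def as_matrix(self) -> np.ndarray:
        return self.matrix

    def apply(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return (self.matrix[:3, :3] @ points.T).T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform3D":
        try:
            inv = np.linalg.inv(self.matrix)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise InvalidTransformError("singular transform") from exc
        return AffineTransform3D(inv)


IDENTITY = RigidTransform3D()


def _transform_matrix(transform) -> np.ndarray:
    if transform is None:
        return np.eye(4)
    return np.asarray(transform.as_matrix(), dtype=np.float64)


def resample(
    volume: ImageVolume,
    transform,
    target: ImageVolume,
    interpolation: str = "linear",
    background: float = 0.0,
    return_mask: bool = False,
):
    """Pull-resample ``volume`` onto the geometry of ``target``.

    ``transform`` maps target-space world points into ``volume``'s world
    space; ``None`` means identity.  Out-of-field voxels are set to
    ``background`` and flagged in the optional mask.
    """
    if interpolation not in ("linear", "nearest"):
        raise InvalidParameterError(f"unknown interpolation {interpolation!r}")
    tmat = _transform_matrix(transform)
    if abs(np.linalg.det(tmat[:3, :3])) < 1e-15:
        raise InvalidTransformError("singular resampling transform")
    # full map: target index -> target world -> source world -> source index
    full = np.linalg.inv(volume.index_to_world_matrix()) @ tmat @ target.index_to_world_matrix()
    shape = target.shape
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    src = full[:3, :3] @ idx + full[:3, 3:4]
    order = 1 if interpolation == "linear" else 0
    values = ndimage.map_coordinates(volume.voxels, src, order=order, mode="constant", cval=background)
    upper = (np.array(volume.shape, dtype=np.float64) - 1)[:, None]
    if order == 1:
        in_field = np.all((src >= 0) & (src <= upper), axis=0)
    else:  # nearest: valid wherever the point rounds to a grid voxel
        in_field = np.all((src >= -0.5) & (src < upper + 0.5), axis=0)
    values = np.where(in_field, values, background)
    out = target.copy_geometry(values.reshape(shape))
    if return_mask:
        return out, in_field.reshape(shape)
    return out


def rigid_from_matrix(matrix, center=None) -> RigidTransform3D:
    """Recover a rigid transform from a 4x4 matrix (rotation must be pure)."""
    m = np.asarray(matrix, dtype=np.float64)
    r = m[:3, :3]
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-6):
        raise InvalidTransformError("matrix is not rigid")
    c = np.zeros(3) if center is None else np.asarray(center, float)
    angles = Rotation.from_matrix(r).as_euler("xyz", degrees=True)
    trans = m[:3, 3] - c + r @ c
    return RigidTransform3D(angles, trans, c)


def random_rigid(rng: np.random.Generator, max_rot: float = 180.0, max_trans: float = 50.0,
                 center=None) -> RigidTransform3D:
    """Uniformly random rigid transform, mainly for tests."""
    rot = rng.uniform(-max_rot, max_rot, 3)
    trans = rng.uniform(-max_trans, max_trans, 3)
    c = np.zeros(3) if center is None else np.asarray(center, float)
    return RigidTransform3D(rot, trans, c)


def save_transform(path, transform) -> None:
    """Write a transform as one row-major 4x4 matrix in plain text."""
    np.savetxt(str(path), _transform_matrix(transform).reshape(1, 16))


def load_transform(path) -> AffineTransform3D:
    m = np.loadtxt(str(path)).reshape(4, 4)
    return AffineTransform3D(m)
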