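"""Separable point-spread-function forward model.

The PSF maps high-resolution voxels to one acquired low-resolution pixel:
a truncated-Taylor sinc windowed by a Gaussian in-plane (FWHM = in-plane
pixel spacing) and a Gaussian slice profile through-plane (FWHM = slice
thickness).  The sinc series

    sinc(x) = 1 - x^2/3! + x^4/5! - x^6/7! + ...

is truncated adaptively so the Lagrange remainder bound stays below a
relative error ``epsilon`` everywhere on the support.  Negative sinc lobes
are clipped to zero so discretized footprint weights form a convex
combination after normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import InvalidParameterError

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def taylor_sinc_terms(x_max: float, epsilon: float) -> int:
    """Smallest number of Taylor terms with remainder <= epsilon on [0, x_max].

    The alternating series for sin(x)/x has Lagrange remainder bounded by
    the first dropped term, ``x^(2n) / (2n+1)!`` after ``n`` terms.
    """
    if epsilon <= 0:
        raise InvalidParameterError("epsilon must be positive")
    n = 1
    while x_max ** (2 * n) / math.factorial(2 * n + 1) > epsilon:
        n += 1
        if n > 200:  # pragma: no cover - unreachable for sane inputs
            raise InvalidParameterError("epsilon too small for float64 series")
    return n


def taylor_sinc(x, n_terms: int):
    """Truncated Taylor approximation of sin(x)/x (value 1 at x = 0)."""
    x = np.asarray(x, dtype=np.float64)
    out = np.zeros_like(x)
    x2 = x * x
    term = np.ones_like(x)
    sign = 1.0
    for k in range(n_terms):
        if k > 0:
            term = term * x2 / ((2 * k) * (2 * k + 1))
        out = out + sign * term
        sign = -sign
    return out


@dataclass
class PSFModel:
    """Separable PSF for one acquisition geometry.

    Offsets are expressed in the slice coordinate frame: axes 0 and 1 are
    in-plane, axis 2 is through-plane.  ``support_radius`` is a hard mm
    cutoff; by default twice the largest voxel extent.
    """

    in_plane_fwhm: np.ndarray
    through_plane_fwhm: float
    epsilon: float = 1e-6
    taylor_terms: int | None = None
    support_radius: float | None = None

    def __post_init__(self) -> None:
        self.in_plane_fwhm = np.broadcast_to(
            np.asarray(self.in_plane_fwhm, dtype=np.float64), (2,)
        ).copy()
        self.through_plane_fwhm = float(self.through_plane_fwhm)
        if np.any(self.in_plane_fwhm <= 0) or self.through_plane_fwhm <= 0:
            raise InvalidParameterError("FWHM values must be positive")
        if self.epsilon <= 0:
            raise InvalidParameterError("epsilon must be positive")
        if self.support_radius is None:
            self.support_radius = 2.0 * max(self.in_plane_fwhm.max(), self.through_plane_fwhm)
        self.support_radius = float(self.support_radius)
        if self.taylor_terms is None:
            # worst-case sinc argument on the support
            x_max = math.pi * self.support_radius / self.in_plane_fwhm.min()
            self.taylor_terms = taylor_sinc_terms(x_max, self.epsilon)

    # per-axis cutoffs: the spherical support scaled by each axis' share
    def axis_cutoffs(self) -> np.ndarray:
        fwhm = np.array([self.in_plane_fwhm[0], self.in_plane_fwhm[1], self.through_plane_fwhm])
        return self.support_radius * fwhm / fwhm.max()

    def weight(self, offsets) -> np.ndarray:
        """Unnormalized PSF weight at slice-frame offsets (mm), shape (..., 3)."""
        offsets = np.asarray(offsets, dtype=np.float64)
        scalar = offsets.ndim == 1
        offs = np.atleast_2d(offsets)
        w = np.ones(offs.shape[0])
        for ax in range(2):
            fwhm = self.in_plane_fwhm[ax]
            x = math.pi * offs[:, ax] / fwhm
            s = taylor_sinc(x, self.taylor_terms)
            np.clip(s, 0.0, None, out=s)
            sigma = fwhm * _FWHM_TO_SIGMA
            w *= s * np.exp(-0.5 * (offs[:, ax] / sigma) ** 2)
        sigma_z = self.through_plane_fwhm * _FWHM_TO_SIGMA
        w *= np.exp(-0.5 * (offs[:, 2] / sigma_z) ** 2)
        w[np.linalg.norm(offs, axis=1) > self.support_radius] = 0.0
        return w[0] if scalar else w


def psf_weight(offset, model: PSFModel) -> np.ndarray:
    """Functional form of :meth:`PSFModel.weight`."""
    return model.weight(offset)


@dataclass
class PSFFootprint:
    """Discretized PSF sampling stencil in the slice frame.

    ``offsets`` (M, 3) are slice-frame sample offsets in mm on a lattice of
    step ``step``; ``weights`` (M,) the unnormalized PSF weights, pruned of
    negligible entries.  Per-pixel normalization to unit sum happens where
    the stencil is applied, after out-of-field samples are dropped.
    """

    offsets: np.ndarray
    weights: np.ndarray
    step: np.ndarray


def discretize_psf(model: PSFModel, step, prune: float = 5e-3) -> PSFFootprint:
    """Sample the PSF on a slice-frame lattice with the given mm step.

    ``prune`` removes lattice points whose weight is below that fraction of
    the peak; they would contribute nothing after normalization.
    """
    step = np.broadcast_to(np.asarray(step, dtype=np.float64), (3,)).copy()
    if np.any(step <= 0):
        raise InvalidParameterError("lattice step must be positive")
    cut = model.axis_cutoffs()
    radii = np.maximum(np.ceil(cut / step).astype(int), 0)
    axes = [np.arange(-r, r + 1) * s for r, s in zip(radii, step)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    w = model.weight(grid)
    keep = w > prune * w.max()
    return PSFFootprint(grid[keep], w[keep], step)
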