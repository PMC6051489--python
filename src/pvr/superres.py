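"""Regularized super-resolution of the HR volume from registered patches.

The objective is

    sum_s  p p-hat (y_s - y*_s)^2
        + lambda * sum_i sum_d phi((x_{i+d} - x_i) / (delta |d|)),

where y*_s is the PSF-simulated patch (a convex combination of HR voxels,
see :mod:`pvr.forward`), p and p-hat the EM inlier posteriors, d runs over
the 26-neighbourhood and phi(t) = 2 sqrt(1 + t^2) - 2 is an
edge-preserving penalty (quadratic near 0, asymptotically linear).  The
residual-scatter gradient of the data term uses the same normalized PSF
weights as the simulation, so forward and adjoint operators are exact
transposes; the regularization weight starts at 0.8 delta^2 and is halved
after every outer iteration.  Descent steps are protected by a
backtracking line search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .forward import (
    FootprintEntries,
    build_footprint_entries,
    scatter_to_volume,
    simulate_from_entries,
    simulate_patch,  # noqa: F401  (re-export: part of the SR surface)
)
from .geometry import ImageVolume, InvalidParameterError
from .patches import Patch
from .psf import PSFFootprint, PSFModel, discretize_psf


def phi(t):
    """Edge-preserving penalty 2 sqrt(1 + t^2) - 2 (even, phi(0) = 0)."""
    t = np.asarray(t, dtype=np.float64)
    return 2.0 * np.sqrt(1.0 + t * t) - 2.0


def phi_prime(t):
    t = np.asarray(t, dtype=np.float64)
    return 2.0 * t / np.sqrt(1.0 + t * t)


def lambda_schedule(delta: float, iteration: int, factor: float = 0.8) -> float:
    """Regularization weight: ``factor * delta**2`` halved every iteration."""
    if delta <= 0:
        raise InvalidParameterError("delta must be positive")
    return factor * delta * delta / (2.0 ** iteration)


# 13 unique offsets; each unordered neighbour pair appears twice in the
# 26-neighbourhood sum, hence the factor 2 in energy and gradient.
_DIRECTIONS = [d for d in itertools.product((0, 1), (-1, 0, 1), (-1, 0, 1))
               if d > (0, 0, 0)]


def _shift_slices(d):
    src, dst = [], []
    for o in d:
        if o >= 0:
            src.append(slice(o, None) if o else slice(None))
            dst.append(slice(None, -o) if o else slice(None))
        else:
            src.append(slice(None, o))
            dst.append(slice(-o, None))
    return tuple(src), tuple(dst)


def regularizer_energy(voxels: np.ndarray, delta: float) -> float:
    e = 0.0
    for d in _DIRECTIONS:
        src, dst = _shift_slices(d)
        norm = delta * np.linalg.norm(d)
        e += 2.0 * phi((voxels[src] - voxels[dst]) / norm).sum()
    return float(e)


def regularizer_gradient(voxels: np.ndarray, delta: float) -> np.ndarray:
    g = np.zeros_like(voxels)
    for d in _DIRECTIONS:
        src, dst = _shift_slices(d)
        norm = delta * np.linalg.norm(d)
        dp = phi_prime((voxels[src] - voxels[dst]) / norm) * (2.0 / norm)
        g[src] += dp
        g[dst] -= dp
    return g


@dataclass
class ObservationBundle:
    """All patch observations concatenated against one HR grid.

    Per global pixel: acquired intensity ``y``, posterior weight ``pw``
    (p times p-hat of its patch), validity.  ``entries`` is the combined
    sparse pixel->voxel table; ``patch_slices`` maps each patch to its
    pixel range so posteriors can be pushed back per patch.
    """

    entries: FootprintEntries
    y: np.ndarray
    pw: np.ndarray
    patch_slices: list[tuple[int, int]]
    volume_shape: tuple[int, int, int]

    @property
    def n_pixels(self) -> int:
        return self.entries.n_pixels

    def simulate(self, volume: ImageVolume) -> np.ndarray:
        return simulate_from_entries(volume, self.entries)

    def scatter(self, values: np.ndarray) -> np.ndarray:
        flat = scatter_to_volume(values, self.entries, self.volume_shape)
        return flat.reshape(self.volume_shape)

    def confidence(self) -> np.ndarray:
        ones = np.ones(self.n_pixels)
        return self.scatter(ones)

    def set_posteriors(self, patches: list[Patch]) -> None:
        for (start, stop), patch in zip(self.patch_slices, patches):
            p = patch.posterior_map if patch.posterior_map is not None else 1.0
            w = p * patch.patch_posterior if patch.included else 0.0
            self.pw[start:stop] = w


def _per_stack_footprints(psf, n_stacks: int, volume: ImageVolume) -> list[PSFFootprint]:
    psfs = [psf] * n_stacks if isinstance(psf, PSFModel) else list(psf)
    return [discretize_psf(p, step=min(volume.spacing)) for p in psfs]


def build_bundle(patches: list[Patch], stacks: list[ImageVolume],
                 volume: ImageVolume, psf,
                 footprint: PSFFootprint | None = None) -> ObservationBundle:
    """Assemble the global sparse forward model for the given patch poses.

    ``psf`` is one :class:`PSFModel` shared by all stacks or a sequence
    with one model per stack.
    """
    footprints = [footprint] * len(stacks) if footprint is not None \
        else _per_stack_footprints(psf, len(stacks), volume)
    pix_ids, voxs, ws, valids = [], [], [], []
    ys, slices = [], []
    offset = 0
    for patch in patches:
        e = build_footprint_entries(volume, patch, stacks[patch.stack_id],
                                    footprints[patch.stack_id])
        pix_ids.append(e.pixel_id + offset)
        voxs.append(e.voxel_flat)
        ws.append(e.weight)
        valids.append(e.valid)
        ys.append(patch.values)
        slices.append((offset, offset + e.n_pixels))
        offset += e.n_pixels
    entries = FootprintEntries(
        np.concatenate(pix_ids), np.concatenate(voxs), np.concatenate(ws),
        np.concatenate(valids), offset)
    bundle = ObservationBundle(entries, np.concatenate(ys), np.ones(offset),
                               slices, volume.shape)
    bundle.set_posteriors(patches)
    return bundle


def initialize_volume(bundle: ObservationBundle, grid: ImageVolume) -> "SRState":
    """Confidence-weighted PSF scatter of all observations onto the grid.

    Voxels no observation reaches are filled with the foreground median of
    the acquired data and carry zero confidence.
    """
    den = bundle.scatter(bundle.pw)
    num = bundle.scatter(bundle.pw * np.nan_to_num(bundle.y))
    vox = np.empty(grid.shape)
    covered = den > 0
    vox[covered] = num[covered] / den[covered]
    y = bundle.y[np.isfinite(bundle.y) & (bundle.pw > 0)]
    fill = float(np.median(y[y > 0.05 * y.max()])) if y.size and y.max() > 0 else 0.0
    vox[~covered] = fill
    volume = grid.copy_geometry(vox)
    return SRState(volume=volume, confidence=den)


@dataclass
class SRState:
    """Current reconstruction, its per-voxel confidence and schedule state.

    While ``lambda0_factor`` is set, ``lam`` follows the schedule
    ``lambda0_factor * delta**2 / 2**iteration`` where ``iteration``
    counts accepted gradient-descent steps; set it to None to control
    ``lam`` manually.
    """

    volume: ImageVolume
    confidence: np.ndarray
    delta: float = 150.0
    lam: float = field(default=0.0)
    lambda0_factor: float | None = 0.8
    iteration: int = 0
    last_step_rejected: bool = False

    def __post_init__(self) -> None:
        if self.lam == 0.0 and self.lambda0_factor is not None:
            self.lam = lambda_schedule(self.delta, 0, self.lambda0_factor)


def data_term(bundle: ObservationBundle, volume: ImageVolume) -> float:
    sim = bundle.simulate(volume)
    ok = bundle.entries.valid & np.isfinite(bundle.y)
    r = np.where(ok, bundle.y - sim, 0.0)
    return float(np.sum(bundle.pw * r * r))


def data_gradient(bundle: ObservationBundle, volume: ImageVolume) -> np.ndarray:
    sim = bundle.simulate(volume)
    ok = bundle.entries.valid & np.isfinite(bundle.y)
    r = np.where(ok, bundle.y - sim, 0.0)
    return bundle.scatter(-2.0 * bundle.pw * r)


def objective(bundle: ObservationBundle, volume: ImageVolume, lam: float,
              delta: float) -> float:
    return data_term(bundle, volume) + lam * regularizer_energy(volume.voxels, delta)


def sr_step(state: SRState, bundle: ObservationBundle, step0: float = 1.0,
            max_backtracks: int = 8) -> SRState:
    """One accepted gradient-descent update of the HR volume.

    The raw gradient is normalized by the voxel confidence (PSF weight
    mass) so the step size is meaningful across unevenly sampled regions;
    backtracking halves the step until the objective decreases.  If it
    never does, the step is rejected and flagged.
    """
    vol = state.volume
    if state.lambda0_factor is not None:
        state.lam = lambda_schedule(state.delta, state.iteration, state.lambda0_factor)
    g = data_gradient(bundle, vol) + state.lam * regularizer_gradient(vol.voxels, state.delta)
    scale = np.maximum(state.confidence, 1.0)
    g = g / scale
    f0 = objective(bundle, vol, state.lam, state.delta)
    eta = step0
    for _ in range(max_backtracks + 1):
        trial = vol.copy_geometry(vol.voxels - eta * g)
        if objective(bundle, trial, state.lam, state.delta) < f0:
            state.volume = trial
            state.iteration += 1
            state.last_step_rejected = False
            return state
        eta *= 0.5
    state.last_step_rejected = True
    return state
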