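"""EM inlier/outlier classification of residuals and the rigidity map.

Residuals e = y - y* between acquired and PSF-simulated intensities are
modelled as a mixture of a zero-mean Gaussian (correctly matched, rigidly
moving data) with variance sigma^2 and mixing proportion c, and a uniform
outlier density m = 1 / (max e - min e).  The E-step posterior for a
pixel being an inlier is

    p = G_sigma(e) c / (G_sigma(e) c + m (1 - c)),

the M-step re-estimates sigma^2 (posterior-weighted mean of e^2, the
Gaussian is pinned at zero mean) and c (mean posterior).  A patch's
aggregate posterior is p-hat = sqrt(mean p^2); patches with p-hat below
0.5 are excluded from super-resolution but keep being re-registered and
may re-enter.  Projecting p * p-hat through the reconstruction PSF gives
a per-voxel rigidity/uncertainty map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import build_footprint_entries, scatter_to_volume
from .geometry import ImageVolume, InvalidParameterError
from .patches import Patch
from .psf import PSFFootprint, PSFModel, discretize_psf


@dataclass
class EMState:
    """Mixture parameters of the residual model."""

    sigma2: float
    c: float = 0.9
    m: float = 0.0
    converged: bool = False
    degenerate: bool = False
    n_iterations: int = 0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise InvalidParameterError("sigma2 must be positive")
        if not 0.0 <= self.c <= 1.0:
            raise InvalidParameterError("c must lie in [0, 1]")


def initial_em_state(errors: np.ndarray, c0: float = 0.9) -> EMState:
    errors = np.asarray(errors, dtype=np.float64)
    var = float(np.var(errors))
    return EMState(sigma2=max(var, 1e-12), c=c0)


def _gaussian(e: np.ndarray, sigma2: float) -> np.ndarray:
    return np.exp(-0.5 * e * e / sigma2) / np.sqrt(2.0 * np.pi * sigma2)


def posterior(errors: np.ndarray, state: EMState) -> np.ndarray:
    """E-step: inlier posterior per residual for a fixed mixture state."""
    e = np.asarray(errors, dtype=np.float64)
    if state.c >= 1.0:
        return np.ones_like(e)
    if state.c <= 0.0:
        return np.zeros_like(e)
    g = _gaussian(e, state.sigma2)
    num = g * state.c
    return num / (num + state.m * (1.0 - state.c))


def log_likelihood(errors: np.ndarray, state: EMState) -> float:
    e = np.asarray(errors, dtype=np.float64)
    mix = _gaussian(e, state.sigma2) * state.c + state.m * (1.0 - state.c)
    return float(np.sum(np.log(np.maximum(mix, 1e-300))))


def em_update(errors: np.ndarray, state: EMState | None = None,
              tol: float = 1e-4, max_iterations: int = 20):
    """Fit the Gaussian + uniform mixture; returns (posteriors, state).

    Iterates E/M until the change in c drops below ``tol``.  If all
    residuals coincide the uniform density is undefined: every pixel is
    declared an inlier and the state flagged degenerate.
    """
    e = np.asarray(errors, dtype=np.float64).ravel()
    e = e[np.isfinite(e)]
    if e.size < 2:
        raise InvalidParameterError("need at least two residuals")
    span = float(e.max() - e.min())
    if state is None:
        state = initial_em_state(e)
    if span <= 0:
        state.degenerate = True
        state.converged = True
        return np.ones_like(e), state
    state.m = 1.0 / span
    p = posterior(e, state)
    for it in range(max_iterations):
        c_old = state.c
        # M-step
        psum = p.sum()
        state.sigma2 = max(float((p * e * e).sum() / max(psum, 1e-300)), 1e-12)
        state.c = float(np.clip(p.mean(), 1e-6, 1.0 - 1e-6))
        # E-step
        p = posterior(e, state)
        state.n_iterations = it + 1
        if abs(state.c - c_old) < tol:
            state.converged = True
            break
    return p, state


def patch_posterior(p_values: np.ndarray) -> float:
    """Root-mean-square aggregate p-hat = sqrt(sum p^2 / N)."""
    p = np.asarray(p_values, dtype=np.float64).ravel()
    if p.size == 0:
        raise InvalidParameterError("empty patch has no posterior")
    return float(np.sqrt(np.mean(p * p)))


def classify_patches(patches: list[Patch], threshold: float = 0.5) -> None:
    """Binary include/exclude per patch from its aggregate posterior.

    A patch is an outlier when its outlier responsibility exceeds the
    inlier one, i.e. p-hat < 0.5 under the default policy.  Exclusion
    zeroes the patch's SR weight only; it stays registered.
    """
    for patch in patches:
        patch.included = bool(patch.patch_posterior >= threshold)


def update_patch_posteriors(patches: list[Patch], residuals_per_patch: list[np.ndarray],
                            state: EMState | None = None,
                            exclusion_threshold: float = 0.5,
                            foreground_threshold: float | None = None):
    """Global EM over all patch residuals, pushed back per patch.

    The uniform density range is estimated over currently included
    patches only, so an already excluded extreme outlier cannot flatten
    it permanently.  When ``foreground_threshold`` is given, the mixture
    is fitted on informative pixels only — those whose acquired intensity
    or residual magnitude exceeds the threshold; quiet background pixels
    (zero observed, zero residual) are trivially consistent and count as
    inliers, instead of collapsing the Gaussian onto their zero spike.
    Returns the fitted :class:`EMState`.
    """
    def informative(patch, res):
        ok = np.isfinite(res)
        if foreground_threshold is None:
            return ok
        return ok & ((np.abs(patch.values) > foreground_threshold)
                     | (np.abs(np.nan_to_num(res)) > foreground_threshold))

    masks = [informative(p, r) for p, r in zip(patches, residuals_per_patch)]
    included = [r[m] for p, r, m in zip(patches, residuals_per_patch, masks) if p.included]
    pool = np.concatenate(included) if included else np.array([])
    if pool.size < 2:
        pool = np.concatenate([r[m] for r, m in zip(residuals_per_patch, masks)])
    if pool.size < 2:
        pool = np.concatenate([r[np.isfinite(r)] for r in residuals_per_patch])
    _, state = em_update(pool, state)
    for patch, res, m in zip(patches, residuals_per_patch, masks):
        finite = np.isfinite(res)
        p = np.zeros(len(res))
        p[finite] = 1.0  # quiet pixels are consistent by definition
        p[m] = posterior(res[m], state) if not state.degenerate else 1.0
        patch.posterior_map = p
        patch.patch_posterior = patch_posterior(p[finite]) if finite.any() else 0.0
    classify_patches(patches, exclusion_threshold)
    return state


def posterior_table(patches: list[Patch]):
    """Per-patch posterior summary as a DataFrame (one row per patch)."""
    import pandas as pd

    rows = [{"stack": p.stack_id, "slice": p.slice_index, "patch": i,
             "scale": p.scale_index, "n_pixels": p.n_pixels,
             "patch_posterior": p.patch_posterior, "included": p.included}
            for i, p in enumerate(patches)]
    return pd.DataFrame(rows)


@dataclass
class RigidityMap:
    """Per-voxel combined inlier posterior on the HR grid, in [0, 1]."""

    volume: ImageVolume


def build_rigidity_map(patches: list[Patch], stacks: list[ImageVolume],
                       grid: ImageVolume, psf,
                       footprint: PSFFootprint | None = None) -> RigidityMap:
    """PSF-weighted average of p * p-hat over all contributing pixels.

    Voxels no patch reaches are 0.  High values mark regions whose motion
    was consistent with the rigid patch model; the map doubles as an
    uncertainty visualization and a candidate mask for SVR refinement.
    ``psf`` is one model shared by all stacks or a per-stack sequence.
    """
    if footprint is not None:
        footprints = [footprint] * len(stacks)
    else:
        psfs = [psf] * len(stacks) if isinstance(psf, PSFModel) else list(psf)
        footprints = [discretize_psf(p, step=min(grid.spacing)) for p in psfs]
    num = np.zeros(int(np.prod(grid.shape)))
    den = np.zeros_like(num)
    for patch in patches:
        e = build_footprint_entries(grid, patch, stacks[patch.stack_id],
                                    footprints[patch.stack_id])
        p = patch.posterior_map if patch.posterior_map is not None \
            else np.ones(patch.n_pixels)
        scatter_to_volume(np.asarray(p, float) * patch.patch_posterior, e, grid.shape, out=num)
        scatter_to_volume(np.ones(patch.n_pixels), e, grid.shape, out=den)
    vals = np.zeros_like(num)
    covered = den > 0
    vals[covered] = num[covered] / den[covered]
    return RigidityMap(grid.copy_geometry(np.clip(vals.reshape(grid.shape), 0.0, 1.0)))
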