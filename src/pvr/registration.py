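"""Stack initialization and rigid 2D-patch-to-3D-volume registration.

Similarity is normalized cross-correlation (CC) throughout, evaluated on
in-field pixels only.  The optimizer is a derivative-free coordinate
descent over the six rigid parameters with directional line-stepping and
a coarse-to-fine step schedule, run over a multi-resolution pyramid for
3D-3D alignment.  CC is well suited here because all stacks are
intensity-matched first; the PSF-resampled objective is piecewise smooth
at best, which rules out gradient-based schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .forward import trilinear_sample
from .geometry import ImageVolume, InvalidParameterError, RigidTransform3D
from .patches import Patch
from .psf import PSFModel, discretize_psf


@dataclass
class RegistrationResult:
    transform: RigidTransform3D
    similarity: float
    converged: bool
    iterations_used: int


def normalized_cc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two equally shaped intensity arrays."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    sa, sb = a.std(), b.std()
    if sa <= 0 or sb <= 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


# ---------------------------------------------------------------------------
# stack-level initialization
# ---------------------------------------------------------------------------

def select_template_stack(stacks: list[ImageVolume]) -> int:
    """Pick the stack with the fewest motion artifacts.

    Proxy: mean normalized cross-correlation between consecutive slices —
    inter-slice motion decorrelates neighbours.  Ties break to the lowest
    index.
    """
    if not stacks:
        raise InvalidParameterError("need at least one stack")
    scores = []
    for stack in stacks:
        ccs = []
        for k in range(stack.shape[2] - 1):
            cc = normalized_cc(stack.voxels[:, :, k], stack.voxels[:, :, k + 1])
            if np.isfinite(cc):
                ccs.append(cc)
        scores.append(np.mean(ccs) if ccs else -np.inf)
    return int(np.argmax(scores))


def foreground_median(volume: ImageVolume, threshold_frac: float = 0.05) -> float:
    v = volume.voxels
    vmax = v.max()
    if vmax <= 0:
        raise InvalidParameterError("volume has no positive intensities")
    fg = v[v > threshold_frac * vmax]
    return float(np.median(fg))


def match_intensities(stacks: list[ImageVolume], template_index: int) -> list[ImageVolume]:
    """Gain-only rescaling so every stack's foreground median matches the template's."""
    ref = foreground_median(stacks[template_index])
    out = []
    for i, stack in enumerate(stacks):
        if i == template_index:
            out.append(stack.copy_geometry())
            continue
        gain = ref / foreground_median(stack)
        out.append(stack.copy_geometry(stack.voxels * gain))
    return out


# ---------------------------------------------------------------------------
# derivative-free rigid optimizer
# ---------------------------------------------------------------------------

def _coordinate_descent(fun, p0, step0, step_min, max_evals):
    """Greedy per-parameter line stepping with a halving step schedule.

    Maximizes ``fun``; returns (best params, best value, evals used).
    """
    p = np.asarray(p0, dtype=np.float64).copy()
    best = fun(p)
    evals = 1
    step = float(step0)
    while step >= step_min and evals < max_evals:
        improved_any = True
        while improved_any and evals < max_evals:
            improved_any = False
            for i in range(len(p)):
                for direction in (1.0, -1.0):
                    moved = False
                    while evals < max_evals:
                        trial = p.copy()
                        trial[i] += direction * step
                        val = fun(trial)
                        evals += 1
                        if np.isfinite(val) and val > best + 1e-12:
                            p, best = trial, val
                            moved = improved_any = True
                        else:
                            break
                    if moved:
                        break  # don't retry the opposite direction
        step /= 2.0
    return p, best, evals


def rigid_from_params(params, center) -> RigidTransform3D:
    return RigidTransform3D(rotation=params[:3], translation=params[3:], center=center)


def recenter_rigid(t: RigidTransform3D, center) -> RigidTransform3D:
    """Same mapping, expressed about a different rotation centre."""
    center = np.asarray(center, dtype=np.float64)
    r = t.rotation_matrix()
    m = t.as_matrix()
    trans = m[:3, 3] + r @ center - center
    angles = Rotation.from_matrix(r).as_euler("xyz", degrees=True)
    return RigidTransform3D(angles, trans, center)


# ---------------------------------------------------------------------------
# 3D-3D registration
# ---------------------------------------------------------------------------

def _downsample(volume: ImageVolume, factor: int) -> ImageVolume:
    if factor == 1:
        return volume
    smoothed = ndimage.gaussian_filter(volume.voxels, sigma=0.5 * factor)
    sub = smoothed[::factor, ::factor, ::factor]
    return ImageVolume(sub, volume.spacing * factor, volume.origin, volume.direction)


def register_volume_3d(moving: ImageVolume, fixed: ImageVolume,
                       init: RigidTransform3D | None = None,
                       pyramid_levels=(4, 2, 1), min_overlap: float = 0.25,
                       max_evals_per_level: int = 400) -> RegistrationResult:
    """Rigid 3D-3D alignment maximizing CC over a resolution pyramid.

    The returned transform maps fixed-space world points into the moving
    stack (the pull convention of :func:`pvr.geometry.resample`).
    """
    lo, hi = fixed.world_bounds()
    center = (lo + hi) / 2.0
    if init is None:
        init = RigidTransform3D(center=center)
    else:
        init = recenter_rigid(init, center)
    params = init.parameters()
    total_evals = 0
    best_val = -np.inf
    for level_idx, factor in enumerate(pyramid_levels):
        fx = _downsample(fixed, factor)
        mv = _downsample(moving, factor)
        world = fx.voxel_to_world(np.indices(fx.shape).reshape(3, -1).T)
        fixed_vals = fx.voxels.ravel()

        def objective(p):
            t = rigid_from_params(p, center)
            idx = mv.world_to_voxel(t.apply(world))
            vals, in_field = trilinear_sample(mv.voxels, idx)
            if in_field.mean() < min_overlap:
                return -np.inf
            cc = normalized_cc(vals[in_field], fixed_vals[in_field])
            return cc if np.isfinite(cc) else -np.inf

        step0 = max(4.0 / (level_idx + 1), 0.5)
        step_min = 0.1 if factor == 1 else 0.25 * factor
        params, best_val, ev = _coordinate_descent(
            objective, params, step0, step_min, max_evals_per_level)
        total_evals += ev
    converged = np.isfinite(best_val)
    if not converged:
        return RegistrationResult(init, -np.inf, False, total_evals)
    return RegistrationResult(rigid_from_params(params, center), best_val, True, total_evals)


# ---------------------------------------------------------------------------
# 2D patch to 3D volume registration
# ---------------------------------------------------------------------------

def _registration_footprint(psf: PSFModel, volume: ImageVolume):
    """Light through-plane-only PSF stencil for the similarity measure."""
    fp = discretize_psf(psf, step=(psf.in_plane_fwhm[0], psf.in_plane_fwhm[1],
                                   min(volume.spacing)), prune=5e-2)
    return fp


class _SmoothCache:
    """Smoothed copies of recent volumes, keyed by (live) object identity.

    Entries carry a weak reference so a recycled ``id`` of a dead volume
    can never serve stale data.
    """

    def __init__(self, maxsize: int = 4):
        self._data: dict[tuple, tuple] = {}
        self._order: list[tuple] = []
        self.maxsize = maxsize

    def get(self, volume: ImageVolume, sigma: float) -> np.ndarray:
        import weakref

        key = (id(volume), sigma)
        entry = self._data.get(key)
        if entry is not None and entry[0]() is volume:
            return entry[1]
        smoothed = ndimage.gaussian_filter(volume.voxels, sigma)
        if key not in self._data:
            self._order.append(key)
        self._data[key] = (weakref.ref(volume), smoothed)
        while len(self._order) > self.maxsize:
            self._data.pop(self._order.pop(0), None)
        return smoothed


_smooth_cache = _SmoothCache()


def register_patch_to_volume(patch: Patch, volume: ImageVolume, stack: ImageVolume,
                             psf: PSFModel, step0: float = 2.0, step_min: float = 0.1,
                             max_evals: int = 150, min_overlap: float = 0.5,
                             max_pixels: int = 450, coarse_sigma: float = 1.5,
                             effort: str = "fast") -> RegistrationResult:
    """Refine a patch's rigid pose against the current reconstruction.

    Maximizes CC between the acquired patch and its PSF-simulated
    counterpart (trilinear volume interpolation under a through-plane
    slice-profile stencil), warm-started from the patch's current
    transform.  A translation-only search against a smoothed volume
    widens the capture range before the full 6-parameter refinement.

    ``effort`` selects the refinement strategy: ``"fast"`` (coordinate
    descent, suited to the pipeline's warm-started inner loop) or
    ``"thorough"`` (Nelder-Mead cascade with out-of-plane rotation
    restarts and a finer slice-profile stencil — the out-of-plane tilt
    of a thin patch moves CC by only ~1e-3 over several degrees, so
    cold-start recovery needs this extra work).  Similarity never
    decreases below the warm start.
    """
    if not patch.registerable:
        return RegistrationResult(patch.transform, np.nan, False, 0)
    from .forward import patch_pixel_world  # local to avoid cycle at import time

    pix_world = patch_pixel_world(patch, stack)
    values = patch.values
    if effort == "thorough":
        max_pixels = max(max_pixels, 700)
        min_overlap = min(min_overlap, 0.35)
    if len(values) > max_pixels:  # subsample deterministically for speed
        sel = np.linspace(0, len(values) - 1, max_pixels).astype(int)
        pix_world = pix_world[sel]
        values = values[sel]
    if values.std() <= 0:
        return RegistrationResult(patch.transform, np.nan, False, 0)

    if effort == "thorough":
        fp = discretize_psf(psf, step=(psf.in_plane_fwhm[0], psf.in_plane_fwhm[1],
                                       psf.through_plane_fwhm / 3.0), prune=2e-2)
    else:
        fp = _registration_footprint(psf, volume)
    warm = patch.transform
    center = warm.inverse().apply(pix_world.mean(axis=0))
    init = recenter_rigid(warm, center)
    n = len(values)
    m = len(fp.weights)
    wsum_total = fp.weights.sum()
    # map to continuous voxel indices: idx = Dir^T (p - origin) / spacing
    vox_lin = (volume.direction.T / volume.spacing[:, None])
    vox_off = -vox_lin @ volume.origin

    def make_objective(voxels):
        def objective(p):
            t = rigid_from_params(p, center)
            rot_inv = t.rotation_matrix().T
            pix_recon = (rot_inv @ (pix_world - t.center - t.translation).T).T + t.center
            frame = rot_inv @ stack.direction
            pts = (pix_recon[None, :, :] + (fp.offsets @ frame.T)[:, None, :]).reshape(-1, 3)
            idx = pts @ vox_lin.T + vox_off
            vals, in_field = trilinear_sample(voxels, idx)
            vals = vals.reshape(m, n)
            in_field = in_field.reshape(m, n)
            sim = fp.weights @ (vals * in_field)
            wsum = fp.weights @ in_field
            ok = wsum > 0.4 * wsum_total
            if ok.mean() < min_overlap:
                return -np.inf
            cc = normalized_cc(sim[ok] / wsum[ok], values[ok])
            return cc if np.isfinite(cc) else -np.inf
        return objective

    evals = 0
    params = init.parameters()
    if coarse_sigma > 0:
        coarse = make_objective(_smooth_cache.get(volume, coarse_sigma))

        def translation_only(p_trans):
            full = params.copy()
            full[3:] = p_trans
            return coarse(full)

        if effort == "thorough":
            # exhaustive capture sweep before local refinement
            offsets = np.arange(-5.0, 5.1, 2.5)
            best_q, best_v = params[3:].copy(), translation_only(params[3:])
            for dx in offsets:
                for dy in offsets:
                    for dz in offsets:
                        q = params[3:] + (dx, dy, dz)
                        v = translation_only(q)
                        evals += 1
                        if np.isfinite(v) and v > best_v:
                            best_q, best_v = q, v
            params = params.copy()
            params[3:] = best_q
        p_trans, _, ev = _coordinate_descent(
            translation_only, params[3:], max(step0, 2.0), 0.5, max_evals // 2)
        params = params.copy()
        params[3:] = p_trans
        evals += ev

    fine = make_objective(volume.voxels)
    if effort == "thorough":
        params, best, ev = _nelder_mead_cascade(make_objective, fine, params,
                                                coarse_sigma, volume,
                                                bounds_center=init.parameters())
        evals += ev
    else:
        params, best, ev = _coordinate_descent(fine, params, step0, step_min, max_evals)
        evals += ev
    # never report a pose worse than the warm start
    warm_val = fine(init.parameters())
    if not np.isfinite(best):
        return RegistrationResult(patch.transform, np.nan, False, evals)
    if np.isfinite(warm_val) and warm_val > best:
        return RegistrationResult(init, warm_val, True, evals)
    return RegistrationResult(rigid_from_params(params, center), best, True, evals)


def _nelder_mead_cascade(make_objective, fine, params, coarse_sigma, volume,
                         bounds_center=None, rot_range: float = 10.0,
                         trans_range: float = 8.0):
    """Smoothed NM, native NM, out-of-plane rotation restarts, polish.

    A box around the warm start keeps the nearly-flat tilt directions
    from drifting to distant spurious optima.
    """
    from scipy.optimize import minimize

    lo = hi = None
    if bounds_center is not None:
        span = np.array([rot_range] * 3 + [trans_range] * 3)
        lo, hi = bounds_center - span, bounds_center + span

    def neg(f):
        def g(p):
            if lo is not None and (np.any(p < lo) or np.any(p > hi)):
                return 2.0
            v = f(p)
            return -v if np.isfinite(v) else 2.0
        return g

    evals = 0
    if coarse_sigma > 0:
        coarse = make_objective(_smooth_cache.get(volume, coarse_sigma))
        r = minimize(neg(coarse), params, method="Nelder-Mead",
                     options=dict(fatol=1e-10, xatol=5e-4, maxfev=500))
        params, evals = r.x, evals + r.nfev
    best = minimize(neg(fine), params, method="Nelder-Mead",
                    options=dict(fatol=1e-12, xatol=1e-4, maxfev=500))
    evals += best.nfev
    # restart around the incumbent in the weakly identified tilt axes
    for drx, dry in ((3, 0), (-3, 0), (0, 3), (0, -3),
                     (2, 2), (2, -2), (-2, 2), (-2, -2)):
        x0 = best.x.copy()
        x0[0] += drx
        x0[1] += dry
        r = minimize(neg(fine), x0, method="Nelder-Mead",
                     options=dict(fatol=1e-12, xatol=1e-4, maxfev=250))
        evals += r.nfev
        if r.fun < best.fun:
            best = r
    simplex = best.x[None, :] + np.r_[np.zeros((1, 6)), 0.4 * np.eye(6)]
    r = minimize(neg(fine), best.x, method="Nelder-Mead",
                 options=dict(fatol=1e-13, xatol=2e-5, maxfev=300,
                              initial_simplex=simplex))
    evals += r.nfev
    if r.fun < best.fun:
        best = r
    return best.x, -best.fun, evals
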