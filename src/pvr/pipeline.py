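"""Full patch-to-volume reconstruction loop.

The pipeline mirrors the classic motion-corrected super-resolution
cascade: template-stack selection, global intensity matching, 3D-3D rigid
initialization, then per scale a loop of {patch extraction, patch-to-
volume rigid registration, EM outlier classification, regularized SR}.
The ``svr`` variant uses whole slices as the (single) patch per slice and
reproduces classical slice-to-volume behaviour; the other variants split
slices into overlapping square patches or dilated superpixels, optionally
over a multi-scale schedule.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from . import em as em_mod
from .geometry import ImageVolume, InvalidParameterError, RigidTransform3D, resample
from .patches import (
    Patch,
    SuperpixelParams,
    dilate_superpixels,
    extract_square_patches,
    extract_superpixels,
    multiscale_schedule,
)
from .psf import PSFModel
from .registration import (
    match_intensities,
    register_patch_to_volume,
    register_volume_3d,
    select_template_stack,
)
from .superres import (
    ObservationBundle,
    build_bundle,
    initialize_volume,
    lambda_schedule,
    objective,
    sr_step,
)

VARIANTS = ("svr", "square", "superpixel", "ms-superpixel")


@dataclass
class PipelineConfig:
    """All knobs of one reconstruction run; serializable and hashable."""

    variant: str = "square"
    patch_size: int = 32           # square-patch edge a (px)
    stride: int = 16               # square-patch stride omega (px)
    superpixel_size: int = 16      # SLIC grid step a (px)
    gamma: float = 60.0            # superpixel dilation
    gamma_units: str = "percent"
    compactness: float = 0.1
    multiscale_factor: float = 1.5
    n_scales: int = 3
    iters_per_scale: int = 2
    recon_spacing: float = 1.25    # mm, isotropic HR target
    delta: float = 150.0           # edge threshold (intensity units)
    lambda0_factor: float = 0.8
    sr_inner_iters: int = 7
    sr_step0: float = 1.0
    reg_step0: float = 2.0
    reg_max_evals: int = 150
    reg_min_overlap: float = 0.5
    min_variance_frac: float = 1e-6
    template_index: int | None = None
    show_progress: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidParameterError(f"variant must be one of {VARIANTS}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Audit trail of one run: schedule, EM behaviour, overhead."""

    config_hash: str
    template_index: int = 0
    records: list[dict] = field(default_factory=list)
    n_patches: int = 0
    overhead_pixel_percent: float = 0.0
    stack_transforms: list[list[float]] = field(default_factory=list)
    patch_table: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def count_overhead(patches: list[Patch], stacks: list[ImageVolume]):
    """Patch count and redundant-pixel overhead of an extraction.

    Overhead % = 100 * (sum of patch sizes - unique covered pixels) /
    unique covered pixels; 0 for an exact partition.
    """
    total = 0
    unique: set[tuple[int, int, int, int, int]] = set()
    for p in patches:
        total += p.n_pixels
        for i, j in p.pixels:
            unique.add((p.stack_id, p.slice_index, p.scale_index, int(i), int(j)))
    n_unique = len(unique)
    overhead = 100.0 * (total - n_unique) / n_unique if n_unique else 0.0
    return len(patches), overhead


def make_psfs(stacks: list[ImageVolume]) -> list[PSFModel]:
    return [PSFModel(in_plane_fwhm=s.spacing[:2], through_plane_fwhm=s.spacing[2])
            for s in stacks]


def make_recon_grid(template: ImageVolume, spacing: float) -> ImageVolume:
    """World-axis-aligned isotropic grid covering the template's FOV."""
    lo, hi = template.world_bounds()
    n = np.maximum(np.floor((hi - lo) / spacing).astype(int) + 1, 1)
    return ImageVolume(np.zeros(tuple(n)), np.full(3, float(spacing)), lo)


def _slice_mask_for_stack(mask: ImageVolume | None, stack: ImageVolume):
    if mask is None:
        return None
    m = resample(mask, None, stack, interpolation="nearest")
    return m.voxels > 0.5


def extract_patches_for_scale(stacks: list[ImageVolume], config: PipelineConfig,
                              scale_index: int, a: int,
                              stack_transforms: list[RigidTransform3D],
                              mask: ImageVolume | None = None) -> list[Patch]:
    """All patches of one scale across all stacks and slices."""
    patches: list[Patch] = []
    for sid, stack in enumerate(stacks):
        smask = _slice_mask_for_stack(mask, stack)
        h, w = stack.shape[:2]
        for k in range(stack.shape[2]):
            sl = stack.voxels[:, :, k]
            if config.variant == "svr":
                new = extract_square_patches(sl, a=max(h, w), stride=max(h, w),
                                             stack_id=sid, slice_index=k,
                                             scale_index=scale_index)
            elif config.variant == "square":
                new = extract_square_patches(sl, a=a, stride=config.stride,
                                             stack_id=sid, slice_index=k,
                                             scale_index=scale_index)
            else:
                params = SuperpixelParams(a=a, compactness=config.compactness,
                                          gamma=config.gamma,
                                          gamma_units=config.gamma_units)
                labels = extract_superpixels(sl, params)
                new = dilate_superpixels(labels, params.gamma_pixels(), sl,
                                         stack_id=sid, slice_index=k,
                                         scale_index=scale_index)
            slice_var = sl.var()
            for p in new:
                p.transform = RigidTransform3D(
                    stack_transforms[sid].rotation.copy(),
                    stack_transforms[sid].translation.copy(),
                    stack_transforms[sid].center.copy())
                if smask is not None:
                    keep = smask[p.pixels[:, 0], p.pixels[:, 1], k]
                    if not keep.any():
                        continue
                    p.pixels = p.pixels[keep]
                    p.values = p.values[keep]
                p.registerable = p.values.var() >= config.min_variance_frac * max(slice_var, 1e-30)
                patches.append(p)
    return patches


def _scale_schedule(config: PipelineConfig):
    if config.variant == "svr":
        return [(0, 0, config.iters_per_scale)]
    if config.variant == "square":
        return [(0, config.patch_size, config.iters_per_scale)]
    if config.variant == "superpixel":
        return [(0, config.superpixel_size, config.iters_per_scale)]
    return multiscale_schedule(config.superpixel_size, config.multiscale_factor,
                               config.n_scales, config.iters_per_scale)


def _residuals_per_patch(bundle: ObservationBundle, volume: ImageVolume):
    sim = bundle.simulate(volume)
    res = bundle.y - sim
    return [res[a:b] for a, b in bundle.patch_slices]


def run_reconstruction(config: PipelineConfig, stacks: list[ImageVolume],
                       mask: ImageVolume | None = None):
    """Execute the full loop; returns (volume, rigidity map, manifest).

    Deterministic given the config (the only randomness, the patch
    processing order, is seeded and immaterial because patches are
    registered independently against a frozen volume).
    """
    if not stacks:
        raise InvalidParameterError("at least one stack is required")
    if len(stacks) == 1:
        warnings.warn("single-stack reconstruction is poorly constrained", stacklevel=2)
    rng = np.random.default_rng(config.seed)

    template = config.template_index if config.template_index is not None \
        else select_template_stack(stacks)
    stacks = match_intensities(stacks, template)
    psfs = make_psfs(stacks)

    stack_transforms: list[RigidTransform3D] = []
    for sid, stack in enumerate(stacks):
        if sid == template:
            stack_transforms.append(RigidTransform3D())
            continue
        result = register_volume_3d(stack, stacks[template])
        stack_transforms.append(result.transform if result.converged
                                else RigidTransform3D())

    grid = make_recon_grid(stacks[template], config.recon_spacing)
    obs_range = (min(float(s.voxels.min()) for s in stacks),
                 max(float(s.voxels.max()) for s in stacks))

    # initial volume: PSF scatter of the whole stacks at their global poses
    init_cfg = PipelineConfig(variant="svr", seed=config.seed)
    init_patches = extract_patches_for_scale(stacks, init_cfg, 0, 0,
                                             stack_transforms, mask)
    bundle = build_bundle(init_patches, stacks, grid, psfs)
    state = initialize_volume(bundle, grid)
    state.delta = config.delta
    state.lambda0_factor = config.lambda0_factor
    state.lam = lambda_schedule(config.delta, 0, config.lambda0_factor)
    fg_threshold = 0.02 * (obs_range[1] - obs_range[0])

    manifest = RunManifest(config_hash=config.config_hash(), template_index=template,
                           stack_transforms=[t.as_matrix().reshape(-1).tolist()
                                             for t in stack_transforms])
    em_state = None
    outer = 0
    all_patches: list[Patch] = []
    total_patches = 0
    for scale_index, a, iters in _scale_schedule(config):
        patches = extract_patches_for_scale(stacks, config, scale_index, a,
                                            stack_transforms, mask)
        total_patches += len(patches) * iters  # processed once per outer iteration
        order = rng.permutation(len(patches))
        for _ in range(iters):
            frozen = state.volume
            iterator = order
            if config.show_progress:
                from tqdm import tqdm
                iterator = tqdm(order, desc=f"register scale {scale_index}", leave=False)
            for idx in iterator:
                p = patches[idx]
                if not p.registerable:
                    continue
                result = register_patch_to_volume(
                    p, frozen, stacks[p.stack_id], psfs[p.stack_id],
                    step0=config.reg_step0, max_evals=config.reg_max_evals,
                    min_overlap=config.reg_min_overlap)
                if result.converged:
                    p.transform = result.transform
            bundle = build_bundle(patches, stacks, grid, psfs)
            em_state = em_mod.update_patch_posteriors(
                patches, _residuals_per_patch(bundle, state.volume), None,
                foreground_threshold=fg_threshold)
            bundle.set_posteriors(patches)
            state.confidence = bundle.scatter(bundle.pw)
            for _ in range(config.sr_inner_iters):
                state = sr_step(state, bundle, step0=config.sr_step0)
                if state.last_step_rejected:
                    break
            manifest.records.append({
                "outer_iteration": outer, "scale_index": scale_index,
                "patch_size": a, "n_patches": len(patches),
                "n_included": int(sum(p.included for p in patches)),
                "em_c": float(em_state.c), "em_sigma2": float(em_state.sigma2),
                "objective": objective(bundle, state.volume, state.lam, state.delta),
                "sr_step_rejected": bool(state.last_step_rejected),
            })
            outer += 1
        all_patches = patches

    n_patches, overhead = count_overhead(all_patches, stacks)
    manifest.n_patches = total_patches
    manifest.overhead_pixel_percent = overhead
    manifest.patch_table = em_mod.posterior_table(all_patches).to_dict("records")

    rigidity = em_mod.build_rigidity_map(all_patches, stacks, grid, psfs)
    final = state.volume.copy_geometry(np.clip(state.volume.voxels, *obs_range))
    return final, rigidity, manifest
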