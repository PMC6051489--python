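"""Reconstruction quality metrics: CC, PSNR, SSIM and DSSIM heat maps.

Reference-free evaluation follows the simulate-vs-acquired protocol: the
acquired in-plane slices are assumed motion-free, the reconstruction is
projected back through the PSF and the final transforms, and the two are
compared slice by slice, averaging weighted by evaluated pixel count.
With a ground-truth phantom available the same metrics can instead be
computed directly against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from .forward import simulate_patch
from .geometry import ImageVolume, InvalidParameterError, resample
from .patches import Patch
from .psf import PSFModel

PSNR_INF = float("inf")


def cc_metric(image: np.ndarray, other: np.ndarray) -> float:
    """Normalized cross-correlation; NaN when either image has no variance."""
    a = np.asarray(image, dtype=np.float64).ravel()
    b = np.asarray(other, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise InvalidParameterError("images must share shape")
    sa, sb = a.std(), b.std()
    if sa <= 0 or sb <= 0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def psnr_metric(image: np.ndarray, other: np.ndarray, i_max: float | None = None) -> float:
    """10 log10(I_max^2 / MSE), with I_max the reference image's maximum.

    Identical images yield the +infinity sentinel rather than an error.
    """
    a = np.asarray(image, dtype=np.float64)
    b = np.asarray(other, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidParameterError("images must share shape")
    if i_max is None:
        i_max = float(a.max())
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_INF
    return float(10.0 * np.log10(i_max * i_max / mse))


def ssim_metric(image: np.ndarray, other: np.ndarray, k1: float = 0.01,
                k2: float = 0.03, window: int = 7, gaussian: bool = False,
                data_range: float | None = None):
    """Mean SSIM and the DSSIM heat map (1 - SSIM_local) / 2.

    The dynamic range defaults to that of the reference ``image``;
    stabilizers are c1 = (k1 L)^2 and c2 = (k2 L)^2.
    """
    a = np.asarray(image, dtype=np.float64)
    b = np.asarray(other, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidParameterError("images must share shape")
    if window > min(a.shape):
        raise InvalidParameterError("SSIM window larger than image")
    if data_range is None:
        data_range = float(a.max() - a.min())
        if data_range <= 0:
            data_range = max(float(np.abs(a).max()), 1.0)
    mean, smap = structural_similarity(
        a, b, win_size=window, K1=k1, K2=k2, data_range=data_range,
        gaussian_weights=gaussian, full=True)
    dssim = np.clip((1.0 - smap) / 2.0, 0.0, 1.0)
    return float(mean), dssim


def dssim_metric(image: np.ndarray, other: np.ndarray, **kwargs) -> float:
    mean, _ = ssim_metric(image, other, **kwargs)
    return (1.0 - mean) / 2.0


@dataclass
class MetricReport:
    """Pixel-count-weighted averages plus a per-slice breakdown."""

    psnr: float
    ssim: float
    cc: float
    n_pixels: int
    per_slice: list[dict] = field(default_factory=list)
    missing: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"psnr": self.psnr, "ssim": self.ssim, "cc": self.cc,
                "n_pixels": self.n_pixels, "per_slice": self.per_slice,
                "missing": self.missing}


def _aggregate(rows: list[dict], missing: list[dict]) -> MetricReport:
    if not rows:
        return MetricReport(np.nan, np.nan, np.nan, 0, [], missing)
    n = np.array([r["n_pixels"] for r in rows], dtype=float)
    w = n / n.sum()

    def wavg(key):
        vals = np.array([r[key] for r in rows], dtype=float)
        finite = np.isfinite(vals)
        if not finite.any():
            return np.nan
        return float(np.sum(vals[finite] * w[finite]) / np.sum(w[finite]))

    return MetricReport(wavg("psnr"), wavg("ssim"), wavg("cc"),
                        int(n.sum()), rows, missing)


def evaluate_reconstruction(stacks: list[ImageVolume], recon: ImageVolume,
                            transforms, psf: PSFModel,
                            window: int = 7) -> MetricReport:
    """Reference-free evaluation against the acquired in-plane slices.

    ``transforms`` holds one rigid transform per stack (pull convention),
    the final stack-level pose.  Each acquired slice is simulated from
    ``recon`` through the PSF at that pose and compared with the original;
    slices whose simulation has no in-field support or no variance are
    reported as missing with a reason.
    """
    if len(transforms) != len(stacks):
        raise InvalidParameterError("need one transform per stack")
    rows, missing = [], []
    for sid, stack in enumerate(stacks):
        h, w = stack.shape[:2]
        for k in range(stack.shape[2]):
            sl = stack.voxels[:, :, k]
            patch = Patch(stack_id=sid, slice_index=k,
                          pixels=np.column_stack(np.nonzero(np.ones((h, w), bool))),
                          values=sl.ravel(), transform=transforms[sid])
            sim = simulate_patch(recon, patch, stack, psf).reshape(h, w)
            ok = np.isfinite(sim)
            if ok.sum() < window * window:
                missing.append({"stack": sid, "slice": k, "reason": "no in-field support"})
                continue
            sim_f = np.where(ok, sim, 0.0)
            acq_f = np.where(ok, sl, 0.0)
            cc = cc_metric(acq_f[ok], sim_f[ok])
            if not np.isfinite(cc):
                missing.append({"stack": sid, "slice": k, "reason": "zero variance"})
                continue
            psnr = psnr_metric(acq_f[ok], sim_f[ok], i_max=float(sl.max()))
            ssim, _ = ssim_metric(acq_f, sim_f, window=window)
            rows.append({"stack": sid, "slice": k, "psnr": psnr, "ssim": ssim,
                         "cc": cc, "n_pixels": int(ok.sum())})
    return _aggregate(rows, missing)


def evaluate_against_ground_truth(recon: ImageVolume, truth: ImageVolume,
                                  window: int = 7) -> MetricReport:
    """Reference-based metrics: resample the truth onto the recon grid."""
    truth_on_grid = resample(truth, None, recon, interpolation="linear")
    t = truth_on_grid.voxels
    r = recon.voxels
    rows = []
    for k in range(r.shape[2]):
        tk, rk = t[:, :, k], r[:, :, k]
        if tk.std() <= 0 or rk.std() <= 0:
            continue
        ssim, _ = ssim_metric(tk, rk, window=window,
                              data_range=float(t.max() - t.min()))
        rows.append({"stack": -1, "slice": k,
                     "psnr": psnr_metric(tk, rk, i_max=float(t.max())),
                     "ssim": ssim, "cc": cc_metric(tk, rk),
                     "n_pixels": tk.size})
    return _aggregate(rows, [])


def stack_baseline_report(stacks: list[ImageVolume], truth: ImageVolume,
                          grid: ImageVolume, window: int = 7) -> MetricReport:
    """Metrics of the raw input stacks (trilinearly upsampled) vs the truth.

    This is the "before reconstruction" baseline against which any
    reconstruction is judged.
    """
    reports = [evaluate_against_ground_truth(
        resample(s, None, grid, interpolation="linear"), truth, window=window)
        for s in stacks]
    rows = [r for rep in reports for r in rep.per_slice]
    return _aggregate(rows, [])
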