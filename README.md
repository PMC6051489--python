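# pvr — patch-to-volume reconstruction for motion-corrupted MRI

Fast 2D multi-slice MRI produces sharp in-plane snapshots, but motion
between slice acquisitions destroys 3D coherence: orthogonal views of the
stacked volume show streaky misalignment.  Slice-to-volume registration
(SVR) repairs this by rigidly registering each slice to an iteratively
super-resolved isotropic volume — but it assumes *whole slices* move
rigidly, which breaks for large fields of view with independently moving
structures (fetal body and placenta, multiple fetuses, moving limbs).

`pvr` implements **patch-to-volume reconstruction**: slices are split
into overlapping patches — squares of edge `a` on a stride-`ω` lattice,
or SLIC superpixels dilated by `γ` pixels — and each patch is registered
rigidly on its own.  The high-resolution volume `X` is estimated by
gradient descent on

    Σ_s p·p̂ (y_s − y*_s)²  +  λ Σ_i Σ_d φ((x_{i+d} − x_i)/(δ|d|)),
    φ(t) = 2√(1+t²) − 2,   λ = 0.8 δ² halved each iteration,

where `y*_s` is the patch simulated from `X` through a separable PSF
(truncated-Taylor sinc in-plane, Gaussian slice profile through-plane)
and `p, p̂` are per-pixel and per-patch inlier posteriors from an EM fit
of a Gaussian + uniform mixture on the residuals — inconsistent data is
depreciated or rejected automatically.  A rigidity map (the posteriors
projected through the same PSF) visualizes where the rigid-patch
assumption held.  SVR is available as the degenerate variant
"one patch = whole slice" and serves as the built-in baseline.

The package ships a full synthetic evaluation harness: a procedural 3D
phantom, three motion-corruption experiments (rigid translation, bulk
rotation of the upper half, global skew with shear `tan θ`), interleaved
anisotropic stack sampling (1.25×1.25×2.5 mm³), and CC / PSNR / SSIM /
DSSIM quality metrics, both against ground truth and reference-free
(acquired slices vs. their PSF re-simulations).

Intended users: researchers working on retrospective motion correction
and super-resolution reconstruction who need a transparent, serial,
fully-tested reference implementation on synthetic data.

## Worked example

```python
import pvr

# phantom + three orthogonal stacks, slices alternating between the
# motion-free state and a 1-degree global skew
phantom, corrupted, stacks = pvr.make_motion_experiment(
    pvr.MotionSpec("skew", theta_xyz=1.0), size=(48, 48, 48), seed=3)

for variant in ("svr", "square"):
    cfg = pvr.PipelineConfig(variant=variant, patch_size=32, stride=16,
                             recon_spacing=1.5, seed=1)
    volume, rigidity, manifest = pvr.run_reconstruction(cfg, stacks)
    rep = pvr.evaluate_against_ground_truth(volume, phantom)
    print(variant, f"PSNR {rep.psnr:.2f} dB  SSIM {rep.ssim:.3f}  CC {rep.cc:.4f}")

grid = pvr.pipeline.make_recon_grid(stacks[0], 1.5)
base = pvr.stack_baseline_report(stacks, phantom, grid)
print("baseline", f"PSNR {base.psnr:.2f} dB  SSIM {base.ssim:.3f}  CC {base.cc:.4f}")
```

Output from this exact run:

```
svr PSNR 23.64 dB  SSIM 0.929  CC 0.9754
square PSNR 23.92 dB  SSIM 0.935  CC 0.9796
baseline PSNR 20.30 dB  SSIM 0.844  CC 0.9548
```

Both reconstructions clearly beat the corrupted stacks (the baseline),
and the patch-based variant exceeds whole-slice SVR on all three
metrics — the expected ordering when the corruption is non-rigid, since
small patches can locally approximate the skew that a rigid whole-slice
pose cannot.

The same pipeline is scriptable from the shell:

```bash
pvr-sim --size 96 --motion skew --amount 1.0 --out-dir data/
pvr reconstruct --stacks data/stack_axial.nii.gz data/stack_sagittal.nii.gz \
    data/stack_coronal.nii.gz --variant square --patch-size 32 --stride 16 \
    --out recon.nii.gz --rigidity-out rigidity.nii.gz --manifest run.json
pvr-eval --recon recon.nii.gz --stacks data/stack_axial.nii.gz \
    --ground-truth data/phantom.nii.gz
```

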