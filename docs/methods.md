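# Methods

## The reconstruction problem

Fast 2D multi-slice MRI (e.g. ssFSE) acquires sharp in-plane snapshots,
but subject motion between slices destroys through-plane coherence.
Classical slice-to-volume registration (SVR) recovers an isotropic
high-resolution (HR) volume `X` from several anisotropic stacks `Y_i` by
rigidly registering each 2D slice to a progressively super-resolved `X`,
under the forward model `Y = D B T X + n` (motion `T`, PSF blur `B`,
subsampling `D`).  SVR assumes each whole slice moves rigidly, which
fails for large fields of view containing independently moving parts.

Patch-to-volume reconstruction (PVR) relaxes the rigidity assumption to
patch scale: every slice is decomposed into overlapping 2D patches
(squares on a stride lattice, or SLIC superpixels dilated by `gamma`
pixels), each patch carries its own rigid pose, and an EM inlier/outlier
model on the residuals depreciates data that no rigid patch motion can
explain.  SVR is recovered exactly as the degenerate configuration
"one patch = one whole slice", which this package exposes as the `svr`
variant and uses as its comparison baseline.

## Pipeline

1. **Template selection.**  The stack with the highest mean normalized
   cross-correlation (NCC) between consecutive slices is chosen as the
   template (inter-slice motion decorrelates neighbours); ties break to
   the lowest index, and the choice can be overridden.
2. **Intensity matching.**  Every other stack is rescaled by a single
   gain so its foreground median (voxels above 5 % of the stack maximum)
   matches the template's.
3. **3D–3D initialization.**  Each stack is rigidly registered to the
   template by maximizing NCC over a 3-level resolution pyramid with a
   derivative-free coordinate-descent optimizer (finest step
   0.1 mm / 0.1°).
4. **Per scale, per outer iteration:** patch extraction → independent
   rigid registration of every patch against the frozen current volume →
   EM classification of residuals → several gradient-descent
   super-resolution updates of `X`.
5. **Outputs:** the clamped HR volume, a rigidity/uncertainty map, and a
   manifest with per-iteration diagnostics (objective, mixture
   parameters, included-patch counts, overhead).

## Forward model

The PSF is separable in the slice frame: a truncated-Taylor sinc
(`sinc(x) = 1 − x²/3! + x⁴/5! − …`) windowed by a Gaussian of FWHM equal
to the in-plane spacing for the two in-plane axes, and a Gaussian slice
profile of FWHM equal to the slice thickness through-plane.  The series
is truncated adaptively so the Lagrange remainder stays below `epsilon`
(default 1e-6) everywhere on the support (hard cutoff at twice the
largest voxel extent); negative sinc lobes are clipped to zero so that
discretized weights form a convex combination.  The true ssFSE slice
profile is scanner-specific and not available here; the Gaussian
surrogate is the standard substitution in this literature.

Discretization: the PSF is sampled on a slice-frame lattice with step
equal to the HR voxel size, each lattice sample is mapped through the
patch pose and spread **trilinearly** over its 8 surrounding HR voxels,
and the surviving in-field weights are normalized per pixel to sum to
one.  The trilinear spread matters: rounding samples to the nearest
voxel injects up-to-half-voxel position errors that dominate the
residual budget (RMS ≈ 60 intensity units on a motion-free phantom) and
prevent super-resolution from beating plain trilinear upsampling.  The
resulting sparse pixel→voxel weight table drives simulation (gather),
the SR gradient (scatter — the exact transpose), and the rigidity map.

## Super-resolution

`X` minimizes

    sum_s p p̂ (y_s − y*_s)²  +  λ Σ_i Σ_d φ((x_{i+d} − x_i) / (δ|d|)),

with `φ(t) = 2√(1+t²) − 2` (quadratic near zero, asymptotically linear —
edge-preserving), `d` over the 26-neighbourhood, and `δ` the intensity
gradient treated as an edge (default 150 for phantom intensities in
0–1000; useful range roughly 100–400).  `λ` starts at `0.8 δ²` and is
**halved after every accepted gradient-descent iteration**.  Early
iterations are therefore strongly smoothed (suppressing registration
error amplification) and the annealed tail converges toward the data.
Halving per outer (registration) iteration instead leaves λ several
orders of magnitude too large after a typical 2-scale run and
demonstrably pushes reconstruction quality below the corrupted-stack
baseline, which is why the per-descent-step schedule is used.

Gradient steps are confidence-normalized (divided by the per-voxel
accumulated PSF weight mass, floored at 1) and protected by a
backtracking line search halving from `sr.step0 = 1.0` (at most 8
backtracks; a step that never decreases the objective is rejected and
flagged).  Voxels no observation reaches are untouched by the data term,
initialized to the foreground median, and pulled only by the
regularizer.  The default budget is 7 SR iterations per outer iteration
and 2 outer iterations per scale.  Intensities are not clamped during
descent; the final volume is clamped to the observed input range.

## EM outlier model

Residuals `e = y − y*` are modelled as a zero-mean Gaussian (inliers,
variance σ², mixing proportion `c`, initialized at 0.9) plus a uniform
density `m = 1/(max e − min e)` (outliers).  E-step:
`p = G_σ(e)c / (G_σ(e)c + m(1−c))`; M-step: σ² ← posterior-weighted mean
of `e²`, `c` ← mean posterior; iterated until `Δc < 1e-4` (max 20).  The
range for `m` is computed over currently included patches only.  A
patch's aggregate posterior is `p̂ = sqrt(mean p²)`; patches with
`p̂ < 0.5` are excluded from SR (zero weight) but keep being
re-registered and may re-enter.  Voxel posteriors enter SR continuously.

One deviation from the textbook fit: the mixture is estimated on
*informative* pixels only — those whose acquired intensity or residual
magnitude exceeds 2 % of the data range.  The phantom background is
exactly zero, and its zero-residual spike otherwise collapses σ² to near
zero, turning every tissue edge into an "outlier".  Quiet background
pixels are trivially consistent and are assigned `p = 1`.  Real scans
with a noise floor would not need this guard.

The rigidity map projects `p·p̂` through the same PSF onto the HR grid
(normalized weighted average, zero where nothing contributes).  High
values mark regions whose motion was consistent with the rigid patch
model; the map doubles as an uncertainty visualization and as a
candidate mask for subsequent SVR refinement.

## Patch registration

Similarity is NCC between the acquired patch and its PSF-simulated
counterpart (trilinear volume interpolation under a through-plane
slice-profile stencil), evaluated on in-field pixels only; patches with
less than 50 % in-field support or near-zero intensity variance
(< 1e-6 of the slice variance) are skipped with their warm-start pose
retained.  Two effort levels share this objective:

* **fast** (pipeline inner loop): translation-only coordinate descent
  against a σ=1.5-voxel smoothed volume, then full 6-parameter
  coordinate descent (step 2 → 0.1, ≤150 evaluations).  Poses are
  warm-started from the previous iteration, so the basin is close.
* **thorough** (cold-start recovery): a ±5 mm translation grid sweep on
  the smoothed volume, a Nelder-Mead cascade (smoothed then native
  resolution), restarts displaced in the out-of-plane tilt axes, and a
  small-simplex polish, all boxed to ±10° / ±8 mm around the warm start.

The extra machinery exists because a single thin patch barely
constrains its out-of-plane tilt: measured on the phantom, tilting a
32-pixel patch by several degrees changes NCC by only ~1e-3, so the
landscape is a nearly flat, gently curved valley with occasional
spurious optima.  In-plane translation and rotation are well
conditioned.  The reported similarity never falls below the warm-start
similarity.  Registration results are order-independent across patches
(each registers against the frozen volume), so the seeded processing
order is reproducibility bookkeeping only.

## Synthetic study conditions

The built-in phantom is a seeded, piecewise-smooth nested-ellipsoid
"head" (bright shell, textured mid-intensity tissue, dark ventricles, a
bright nucleus and asymmetric blobs; intensities 0–1000) at 1 mm³,
default 96³.  Motion corruption reproduces three experiments: rigid
translation of the whole volume by `d_x` mm along x; bulk rotation of
the upper half (split at the axial mid-plane, boundary slice assigned to
the moving half) by `theta_z` about z; and a global skew whose six
off-diagonal shear entries all equal `tan(theta_xyz)` (refused at
|θ| ≥ 45°), applied about the volume centre.  Stacks are sampled at
1.25×1.25×2.5 mm³ in axial/sagittal/coronal orientation with slices
alternating between the motion-free and corrupted states (even indices
free, odd corrupted — configurable), and the HR target is 1.25 mm
isotropic.  Before resampling onto the stack grid the source volume is
convolved with a Gaussian of FWHM = slice thickness along the slice
axis, emulating thick-slice excitation; without this the synthetic data
contain no through-plane blur and the SR forward model is structurally
mismatched.

What the generator does **not** emulate: measurement noise, intensity
bias fields, k-space/truncation artifacts, continuous (intra-slice)
motion, and real anatomy.  Passing tests therefore demonstrate the
correctness and the relative ordering of the algorithms under
controlled, piecewise-rigid corruption — not clinical performance.

## Problem sizes and numerical choices

End-to-end checks run at desk scale: the skew ordering experiment on a
96³ phantom (the test suite) and 72³ (the acceptance script), bulk
rotation at 64–72³, 30–50 registration-recovery cases.  Tolerances:
forward-model oracle agreement 1e-9; data-gradient finite-difference
agreement 1e-4 relative; PSF weight normalization 1e-9; world↔voxel and
transform round-trips 1e-9 mm.  Ties and degenerate inputs: template
ties → lowest index; EM with identical residuals → all inliers, flagged
degenerate; PSNR of identical images → +inf sentinel; CC of
zero-variance images → reported missing rather than raised.

## Known limitations

* Out-of-plane tilt of individual small patches is weakly identifiable
  (see above); per-axis cold-start recovery to 1° at ±5° perturbation
  succeeds in roughly nine of ten cases but is not guaranteed.
* The Gaussian slice profile and the clipped-sinc in-plane window are
  surrogates; absolute PSNR levels shift with the true scanner PSF.
* The serial implementation favours clarity over speed; patch
  registrations within an outer iteration are independent and could be
  parallelized without changing results.
* Single-stack reconstruction is permitted but poorly constrained
  through-plane (a warning is emitted).
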