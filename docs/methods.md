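# Methods

## Problem

A multi-core fiber (MCF) microendoscope delivers structured light into
tissue: each of its thousands of single-mode cores transmits one piston
phase, so the distal facet acts as a randomly sampled phased array.  A
computer-generated hologram (CGH) displayed on a phase-only SLM sets those
piston phases; the far field at a working distance `z` beyond the facet
then forms the desired intensity pattern.  Because the cores sample the
hologram sparsely and irregularly, holograms computed for a full pixel
grid (classical Gerchberg–Saxton) alias badly; the package implements the
core-aware iterative baseline (Core-GS) and a feed-forward phase-encoder
network trained without labels through a differentiable model of the
fiber and of free-space propagation.

## Physical model

Scalar diffraction uses the band-limited angular spectrum method:

    U_o = IFFT2[ H(u, v) * FFT2[U_i] ],
    H(u, v) = exp(i 2 pi z sqrt(1/lambda^2 - u^2 - v^2))   for |u| <= u_lim, |v| <= v_lim,
    u_lim = 1 / (lambda sqrt((2 du z)^2 + 1)),   du = 1/(N_x px)

with H = 0 outside the window and on evanescent components
(1/lambda^2 < u^2 + v^2).  The window suppresses the spectral components
whose fringes alias over distance z; |H| = 1 inside it, so in-band energy
is conserved exactly and back-propagation is multiplication by conj(H),
making the round trip an in-band identity to machine precision.  The
implementation is verified against a direct O(N^4) DFT-summation oracle
(no FFT) and against single-term Fresnel propagation in the paraxial
limit.

The fiber facet is modeled as a binary amplitude mask: unit-amplitude
disks of radius r at the core centers, zero between cores, each disk
carrying one piston phase.  Phase sampling reads the hologram at the pixel
nearest each core center; rendering paints hard-edged disks (a pixel
belongs to a disk iff its center lies within r).  With r >= pitch/sqrt(2)
every core contains its nearest pixel center, so sampling inverts
rendering exactly — an identity the tests assert.

Intrinsic optical path differences (OPDs) between cores are modeled as a
per-core phase offset layer; digital optical phase conjugation (DOPC) is
the negated layer.  Phase layers stack additively at the facet plane, so
offsets are summed *before* wrapping; a distortion followed by its exact
conjugate cancels bit-for-bit, and the compensated reconstruction equals
the undistorted one identically.

## Desk-scale study conditions

The full system (1920x1080 SLM pixels of 0.4 um, 350 um facet, 10,000
cores, 131,600 training characters) is supported by configuration but is
not what the tests run.  The desk profile scales the system down while
preserving its dimensionless ratios:

| quantity                          | full scale | desk scale |
|-----------------------------------|-----------|------------|
| grid                              | 1920x1080, 0.4 um | 64x64, 2.0 um |
| wavelength / distance             | 532 nm / 700 um | same |
| core radius / spacing             | 1.0 / 3.3 um | 1.5 / 3.5 um |
| areal core fill inside facet      | ~33% | ~33% (facet = 2r sqrt(n/0.33)) |
| facet / grid-window fraction      | 0.46 | ~0.5 |
| speckle grain (lambda z / D) in px| 2.7 | 2.7 |
| content window / padding          | 512^2 in 1920x1080 | 48^2 in 64^2 |

The constant-fill facet rule reproduces the real 350 um facet at 10,000
cores of 1 um radius; at desk scale it gives a 60 um facet for the
128-core training bundle and 75 um for the 200-core comparison bundle.
Two further desk constraints fix the pitch: a single core's diffraction
cone at z = 700 um must cover the target window, and the maximum grating
deflection angle of the pitch must reach the content corners; 2 um
satisfies both at 64x64.

## Synthetic data

Training glyphs emulate handwritten characters without any download:
2–4 strokes of connected quadratic arcs drawn with a round brush
(~2.5 px stroke diameter on a 28x28 canvas, matching typical digit pen
widths), lightly smoothed.  Test-style binary patterns are rectangles,
rings and smiley composites; disks are available for focusing studies.
Images are resized to the 48x48 working window (bilinear), zero-padded
centered into the 64x64 grid and max-normalized — the same flow as the
experiment's 28 -> 512 -> 1920x1080 preprocessing.  Generation is a pure
function of (spec, seed).

What the synthetic data does not capture: the class structure and stroke
statistics of real handwriting, camera noise, and any experimental
registration error.  Passing the desk-scale tests therefore demonstrates
the *mechanisms* (aliasing, core constraint, unsupervised convergence,
orderings between methods), not the absolute fidelity values of the
full-scale system.

## Baselines

Plain GS alternates between unit source amplitude (phase-only constraint)
and the target amplitude, propagating between planes; initialization is
zero phase by default (seeded uniform-random optional); a fixed iteration
budget, no early exit.  Core-GS additionally projects onto the fiber
constraint every iteration: sample the facet phase at the core centers,
re-render piston-phase disks on the binary core mask, then propagate.
Its per-core piston reading (no amplitude freedom inside a disk) is the
minimal constraint-projection variant.  Both are scored through the one
shared reconstruction path (render -> propagate -> |U|^2), so method
comparisons cannot diverge in their forward models.

## The phase-encoder network

The target is back-propagated to the facet plane and split into real and
imaginary planes — mapping within one plane is easier to learn than
across planes — which feed two independent downsampling paths of a
residual U-Net (pre-activation residual blocks; the first convolution of
each resampling block is strided (2,2); transposed convolutions
upsample).  The paths concatenate at the bottleneck; upsampling blocks
receive skip connections from both paths.  The network outputs one
unwrapped phase plane at the modulator grid; the embedded physics
(nearest-pixel core sampling, disk rendering via exp(i phi), propagation,
intensity) turns that into a reconstruction, and the loss is the negative
Pearson correlation (NPCC) with the input target.  The target is its own
label; no hologram is ever precomputed.

Desk defaults (the training protocol — 5 epochs, Adam — is part of the
study conditions; channel counts, learning rate and batch size are free
choices): depth 3, base width
8 doubling per level, batch 6, Adam with lr 3e-3 and cosine decay to
lr/10.  Three desk-motivated design choices:

* **Residual phase-conjugation head.**  Displaying the phase of the
  back-propagated field (digital phase conjugation) is already a strong
  hologram.  When input and output grids coincide the output is
  `head(features) + alpha * angle(U_back)` with a learnable scalar alpha
  initialized at 1; the raw input planes and their polar form (amplitude,
  phase) also enter the two-layer 1x1 head as full-resolution skips.  The
  encoder therefore learns a correction to a physically sensible starting
  point instead of rediscovering it.
* **Per-core calibration vector.**  The hologram is read at the pixel
  nearest each core center; the sub-pixel displacement induces a small
  systematic phase offset per core.  A learnable per-core offset vector
  (one phase per core, trained jointly, stored in the checkpoint and
  painted onto the hologram at the core positions during inference)
  absorbs it — the learned analog of a per-core calibration layer.
* **Width.**  Base width 8 keeps the prescribed 5-epoch / 2000-image run
  at several minutes of one CPU; wider or deeper nets were not better at
  this scale.  Optional weight averaging (EMA) is available but off by
  default: at 5 epochs the loss is still descending and the average lags.

Everything stochastic (initialization, shuffling, core maps, data) takes
explicit seeds; identical config + seed reproduces parameters and
training bit-for-bit.

The engine underneath is a small reverse-mode autodiff on numpy arrays
(strided conv / transposed conv via im2col–GEMM–col2im with numba-compiled
patch kernels, batch norm, ReLU, concat, FFT propagation, complex
rendering, NPCC).  Complex gradients use the real-pair convention, under
which every C-linear op back-propagates through its Hermitian adjoint;
all primitives and the end-to-end pipeline are gradient-checked against
central finite differences at float64.

## Numerical choices

* Evanescent components are zeroed (far-field use; avoids blow-up for
  negative z).
* Frequency grid in FFT order, du = 1/(N px); band-limit window inclusive
  at |u| = u_lim.
* Target images enter as amplitude = sqrt(intensity), zero phase;
  reconstructions are |U|^2 max-normalized before saving (the correlation
  metric is scale-invariant, so normalization affects only display).
* Hologram files: 8-bit PNG with floor quantization of [0, 2 pi) plus a
  lossless float32 TIFF; the float round trip is exact.
* Degenerate inputs error loudly: constant images in the correlation,
  zero-variance targets in training, cores outside the grid, disks that
  cover no pixel, infeasible packings.
* Core placement: random darts with rejection up to ~45% exclusion-disk
  coverage; above that (dense, real-bundle-like regimes) a jittered
  hexagonal lattice is used — random darts jam near 55% coverage, and the
  10,000-core geometry is essentially close-packed.

## Problem sizes in the shipped runs

Tests and the acceptance script run entirely at desk scale: 64x64 grids,
128-core training map, 200-core comparison map, 2000 training glyphs,
200 held-out targets, 5 epochs, two training seeds; iterative baselines
use 100 iterations.  These sizes are the package's default study
conditions; the full-scale geometry remains available through
`full_scale_profile()` and the configuration surface.

## Known limitations

* Hard-edged disks (no sub-pixel anti-aliasing) and uniform per-core
  transmission; no inter-core coupling, multimode cores, or
  bending-dependent OPD drift.
* The in-situ two-stage experimental calibration is represented only by
  its simulated effect (OPD layer + conjugate compensation).
* Desk-scale fidelity values are speckle-limited and lower than the
  full-scale system's (glyph strokes span ~1.6 speckle grains here versus
  ~20 at full scale).  In this regime the per-target iterative Core-GS
  retains a small fidelity edge over the amortized network (mean
  held-out CC 0.73-0.74 for the network vs 0.75-0.77 for Core-GS,
  depending on core-map seed); the network's advantage over
  grid-based GS, its >= 0.7 fidelity and its severalfold speed advantage
  do transfer, but the network-beats-Core-GS ordering belongs to the
  smooth, strongly oversampled full-scale regime.
* On one CPU a single network inference is ~5x faster than 100 Core-GS
  iterations at desk geometry; larger ratios require framework-grade
  convolution kernels or a GPU.
* The network is trained per core map: a new fiber requires retraining.
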