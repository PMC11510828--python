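# Methods

## Problem setting

Clinical MR protocols often acquire anisotropic volumes: high resolution in
the imaging plane, coarse resolution in the through-plane (slice-select)
direction, with a scaling factor *r* = slice thickness / in-plane voxel
size.  Given up to three orthogonal such scans x_v of the same subject, the
goal is to recover the isotropic high-resolution volume y.  The package
implements the full supervised pipeline: simulate the scans from an
isotropic reference, fuse them into a single low-resolution volume on the
isotropic grid, and learn a 3D CNN mapping from the fusion to the
reference under an L1 loss.

Array axes (0, 1, 2) are identified with the sagittal, coronal and axial
slice-select directions throughout.  All volumes are normalized to [0, 1]
on load; this fixes the scale on which the Rician noise level and the PSNR
data range are defined.

## Degradation model

`downsample_axis` models the partial volume effect along one axis: output
slice *j* sits at input coordinate (j + ½)r − ½ and is the normalized
overlap-weighted average of the input slices inside a box window of width
*r* centred there.  The window widens with slice thickness, the weights of
a row sum to one (constants are preserved exactly), and integer and
fractional *r* share the one code path.  Before simulation the reference
volume is cropped per axis to the largest extent that divides cleanly by
*r*, so the down/up round trip is unambiguous.

`upsample_axis` interpolates back to the isotropic grid with a not-a-knot
cubic spline along the degraded axis, with the same extent-aligned
coordinate convention (requesting the current length is the identity).

`fuse_scans` averages the upsampled scans voxelwise.  This fusion *is* the
CubeAvg baseline, and with a single scan it reduces exactly to spline
interpolation of that scan.

Rician noise is applied to the anisotropic scans before upsampling and
fusion, never to the labels: out = sqrt((v + g1)² + g2²) with g1, g2
i.i.d. N(0, (σ/255)²).  σ is quoted on a 0–255 display scale because
values like σ = 5…25 are only meaningful on an 8-bit-like range; at zero
signal the output is Rayleigh with mean (σ/255)·√(π/2), which the tests
use as a closed-form oracle.

## Network

The model maps the fused volume to the reference at the same spatial shape
(inference happens in HR space, so one network handles any — including
fractional — scaling factor).  Architecture:

* feature extraction: 3×3×3 conv, 1 → C channels, no activation;
* *n* concatenation blocks: a wide-activation branch
  Conv(C → eC) → ReLU → Conv(eC → C); the block input scaled by a
  learnable scalar π and the branch output scaled by a learnable scalar λ
  are concatenated along channels and mixed by a 1×1×1 conv with no
  activation (joint linear attention over the linear and nonlinear
  features).  With the 1×1×1 kernel equal to two stacked identity matrices
  and π = λ = 1 the block is exactly a residual connection — an invariant
  the tests assert;
* a global residual skip adds the extracted features to the deep
  features, followed by two 3×3×3 reconstruction convs (C → C → 1).

Defaults: n = 16 blocks, C = 32, expansion e = 4.  Depth along the longest
path is 3n + 4 = 52 layers and the parameter count is 3,604,257 ≈ 3.6 M.
π and λ are initialized to 1.0; ReLU-facing convs use He fan-in
initialization, the remaining convs plain 1/fan-in scaling.  All convs are
zero-padded, stride 1, with biases; there is no normalization layer.

The implementation is pure NumPy.  The fast convolution evaluates k³
shifted (voxels × C_in)·(C_in × C_out) GEMMs over the zero-padded input —
on a single CPU this beats materializing the k³-times-larger im2col patch
matrix — and the backward pass reuses the same loop: the data gradient is
the convolution of the output gradient with the spatially flipped,
channel-transposed kernel.  A literal quadruple-loop reference
implementation of the convolution is kept in the package purely as a test
oracle, and every layer's analytic gradient is checked against finite
differences in the suite.  Checkpoints are .npz archives with the model
configuration embedded.

## Training

Adam (β1 = 0.9, β2 = 0.999, ε = 1e−8) minimizes the mean absolute error
over batches of aligned fused-LR/HR cubes.  The full-scale recipe is batch
8 of 24³ cubes, learning rate 2e−4 halved every 1e5 iterations, 4e5
iterations total; `lr_at` implements the step-decay schedule exactly.
Cubes are sampled uniformly with replacement from the training volumes and
flip-augmented along each axis independently with probability ½.  Training
aborts with a diagnostic if the loss goes non-finite, and a fixed seed
makes runs bit-reproducible on one device.

### Scaled-down recipe

The CPU-sized experiment the demo and the test suite run uses 32³
phantoms, ×2 scaling, a 2-block/16-channel/expansion-4 model, 500
iterations of batch 8 with 14³ cubes, and 8 training volumes with one held
out.  Two deliberate departures from the full-scale hyperparameters, both
consequences of the 800-times-shorter schedule rather than of the
full-scale values being wrong at scale:

* cube size 14 instead of 24 — 24³ cubes barely fit a 32³ volume (no
  sampling diversity) and cost ~5× more per iteration;
* flat learning rate 5e−4 instead of 2e−4 — a rate tuned for 4e5
  iterations cannot move the weights appreciably in 500; over a 500-step
  horizon Adam's total per-parameter displacement is bounded by roughly
  lr·iters, so the initial rate must scale up for the run to converge at
  all, and the first halving breakpoint (1e5) is never reached within the
  short schedule (the rate stays flat).

At this training length the single-pass network is still mid-convergence:
its held-out PSNR oscillates around the fusion baseline + ~0.7 dB, while
the 8-flip self-ensemble — which cancels the anisotropic component of the
remaining optimization noise — sits a stable ~1.3–1.7 dB above the
baseline.  Roughly two to three times as many iterations are needed before
the single pass itself clears a 1 dB margin.

## Inference and evaluation

`super_resolve` fuses the scans and runs the network, optionally in
overlapping tiles: each tile is extended by an 8-voxel margin of real
context, clamped at the volume boundary so the network's own zero padding
applies at the same absolute positions as in a whole-volume pass.  With
the toy model's receptive radius (7 voxels for n = 2) below the margin,
tiled and untiled outputs coincide to floating-point tolerance; for the
52-layer default the margin truncates a receptive field that decays with
distance, and the tiling-consistency test bounds the seam error.

The geometric self-ensemble averages the eight axis-flip round trips
t⁻¹(F(t(x))).  The transform group is flips only — 90° rotations would mix
axes whose degradation histories differ.

Metrics, computed on [0, 1]-normalized volumes:

* **PSNR** with data range 1.0 over the whole volume (no border crop, no
  foreground mask); identical volumes report infinity.
* **SSIM** with a 3D Gaussian window (σ = 1.5, 11³ support, K1 = 0.01,
  K2 = 0.03), averaged over windows fully inside the volume.  The
  implementation (FFT-based local moments) is tested against a literal
  per-window evaluation and against scikit-image's
  `structural_similarity`.
* **Sharpness** as the RMS central-difference gradient magnitude.  The
  quadratic mean is chosen deliberately: smoothing a monotone edge
  preserves its total variation, so a plain mean absolute gradient barely
  responds to through-plane blur (and spline ringing can even raise it),
  whereas the Dirichlet-energy form falls as edge energy spreads.  It is
  linear in intensity scaling and zero on constant volumes.

## Phantoms

`make_phantom` builds piecewise-smooth volumes: a constant background
(0.15), randomly placed and oriented ellipsoids painted with tissue-like
intensities in [0.25, 0.70], optional 2–4-voxel-radius hyperintense lesion
blobs (+0.25, emulating small focal pathology such as MS lesions), then a
light Gaussian smoothing (0.6 voxels by default) and clipping to [0, 1].
Ellipsoid boundaries guarantee intensity edges with gradient components
along all three axes, so through-plane blurring is observable whichever
axis is degraded.  All randomness flows from an explicit per-phantom seed.

What the phantoms do *not* emulate: anatomy, MR contrast physics (TR/TE,
bias fields), scan-to-scan misregistration or brightness differences.
Passing tests therefore demonstrate that the pipeline's machinery —
degradation, fusion, optimization, inference, metrics — behaves as
specified, and that the learned model beats the spline-fusion baseline on
data of this class; they do not certify performance on clinical images.

## Numerical choices and limitations

* Stored dtype float32 everywhere; metric arithmetic in float64.
* Spline evaluation slightly outside the input node range (the half-voxel
  offsets at volume edges) uses the spline's natural extrapolation.
* Cube sampling is uniform with replacement; ties and degenerate inputs
  (constant volumes) are exercised by tests.
* Determinism is promised per device only: BLAS reduction order may differ
  across machines.
* The single-CPU NumPy implementation trains toy models in minutes but is
  not suited to the full-scale 4e5-iteration recipe; the architecture
  accounting (depth, parameter count) covers the full-scale model exactly.
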