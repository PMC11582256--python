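# Methods

This note documents the models, the numerical conventions, the defaults
and the deliberate design choices in `synthraw`, and what the phantom-based
tests do and do not demonstrate about real data.

## Signal model and conventions

A fully sampled 2D multi-coil acquisition of one slice is modelled as

```
raw_j = FFT( M · (P/|P|) · CSM_j ) + n_j ,    j = 1..C coils
```

with `M ≥ 0` the magnitude image, `P` the complex object phase map,
`CSM_j` the complex sensitivity of coil `j` (root-sum-of-squares across
coils equal to 1 over the object), and `n` complex Gaussian noise with
coils×coils covariance `φ`, i.i.d. across k-space samples.

Conventions, fixed package-wide:

- **FFT**: centered (DC at index `n//2`) and orthonormal. Orthonormality
  makes the FFT unitary, so noise statistics are identical in image space
  and k-space; this is what lets the background-patch covariance estimator
  validate noise that was injected in k-space, and what makes the
  variational network's backward FFT pass simply the inverse transform.
- **Axis order** `(slice, coil, ky, kx)`; `ky` is the phase-encoding axis
  that is undersampled.
- **Complex Gaussian convention**: real and imaginary parts each carry
  variance `φ/2`, so the total complex variance per coil is `diag(φ)`.
  Noise is drawn as `L z` with `L` the Cholesky factor of `φ`.
- **Precision**: calibration/synthesis math in complex128; network
  training in float32.
- Raw intensities are assumed pre-scaled to unit order (`scale_raw`,
  default factor 1e6, mirrors the usual normalization of scanner raw
  exports).

## Calibration (map estimation)

`decompose_scan` inverts the signal model for fully sampled data:

1. **Sensitivity estimate**: k-space is windowed to the central
   calibration block (default 26 lines, the same width applied in `kx`,
   Hann-apodized to suppress ringing), inverse-transformed, and divided by
   the root-sum-of-squares of the low-pass coil images. Support is the
   region where the low-pass RSS exceeds 5% of its maximum; maps are zero
   outside. The factorization `M·P·CSM` is only defined up to a smooth
   phase exchanged between `P` and `CSM`; the estimator fixes the
   convention by anchoring the per-pixel phase to coil 0, which attributes
   the common (object) phase to the combined image. A final global-phase
   normalization divides all coils by the circular mean phase of coil 0
   over the support (the circular mean — the argument of the mean unit
   vector — avoids the wrap-around bias of averaging angles directly).
2. **Combination**: `Σ_j conj(CSM_j)·image_j` gives the complex combined
   image; its magnitude is `M`, and the image itself is kept as the
   (magnitude-carrying) phase map, unit-normalized only at synthesis time.
3. **Noise**: the sample covariance of a background patch of the coil
   images. "Manually selected" background is replaced by a deterministic
   search: the 20×20 corner patch with the lowest mean RSS.

Accuracy on noiseless phantoms: magnitude recovered to <0.1%, phase to
<0.03 rad inside support, sensitivities to <5% relative on the support
interior (the one-or-two-pixel boundary ring is partial-volume-limited by
the low-pass estimator and excluded from that comparison).

## Generative models

Both map types (phase: 1 complex channel; sensitivities: `C` complex
channels) use the same architecture, operating on stacked (Re, Im)
channels — 2 for phase, 2·C for sensitivities (32 channels at 16 coils).
Representing the unit phase map as Re/Im avoids angle-wrapping
discontinuities.

**Bi-directional conditional AAE.** The encoder (three stride-2
convolutions + dense head) maps `(M, map)` at the operating resolution to
a 4-element latent vector. The decoder downsamples `M` through a mirror
stack, broadcast-concatenates the latent at the bottleneck, and upsamples
back (nearest-neighbour + convolution). Losses:

| term | form | default weight |
|------|------|----------------|
| map reconstruction | L1 | 1.0 |
| latent adversarial | non-saturating GAN on the latent only | 0.05 |
| reverse consistency | L2 between a random latent and its re-encoding after decoding | 0.5 |

The discriminator is a 3-layer dense net on the latent vector alone, so
adversarial gradients reach only the encoder — there is no image-space
adversarial signal and hence no GAN-style image artifacts by construction.
The reverse path is what keeps one latent mapping to one map; empirically
it is also what keeps sampled maps diverse. Optimizer: Adam, lr 1e-3.
A master seed fans out to (encoder init, decoder init, discriminator init)
and (data order, latent sampling) via `numpy.random.SeedSequence.spawn`.

The AAE operates at fourfold-reduced resolution (80×80 when the native
grid is 320×320; the test scale uses 64→16). The operating grid must be
divisible by 8 (three stride-2 levels). Downsampling is a block mean of
the Re/Im parts (anti-aliased and exactly invertible for constants).

**Super-resolution.** The low-resolution map is bilinearly upsampled and
refined by a 3-layer CNN that also sees the high-resolution magnitude; the
output layer is zero-initialized so the untrained network reproduces plain
bilinear interpolation exactly, and training (L1, Adam lr 5e-4) can only
improve on it. The lower learning rate is deliberate: starting at the
bilinear optimum, 1e-3 oscillates without net gain on smooth maps. The
network's advantage over bilinear interpolation comes from
magnitude-aligned structure (support edges of decomposition-derived maps);
on globally smooth synthetic maps it is only marginally better, because
bilinear is already near-optimal there.

**Sampling.** `sample_map` draws `z ~ N(0, I)`, decodes at low resolution
conditioned on the block-averaged magnitude, and applies the
super-resolution net. Generated sensitivity maps are RSS-normalized before
synthesis so the magnitude image remains the exact RSS ground truth of the
noiseless synthetic slice.

Measured behaviour of the fixed-seed 500-step smoke run (40 phantom
slices, 16×16 operating grid): forward reconstruction loss falls to ~0.18
of its initial value; the mean Kolmogorov–Smirnov distance of the latent
marginals to N(0,1) drops from ~0.40 to ~0.10; latent means lie in
(−0.5, 0.5) and variances in (0.4, 2.5). Regeneration (full auto-encode of
a ground-truth map) reaches ~0.1 relative L2 on training maps but ~0.45 on
held-out maps: a 4-element latent cannot fully span the 7-parameter
phantom phase family from 40 examples, so sampled maps are plausible
rather than reconstructive — which is the intended use.

## Synthesis and pool mixing

`synthesize_raw` evaluates the signal model; `P/|P|` is defined as 1
where `|P|` is numerically zero (background). Noise is added in k-space;
by unitarity this is statistically identical to image-domain noise.

Training data for reconstruction is drawn per sample: with probability
0.75 a slice is synthesized on the fly (random magnitude source, sampled
maps, noise covariance drawn uniformly from the pool of real-scan
estimates), otherwise a stored real slice is returned. Ablation modes
substitute real decomposed maps or sinusoidal phase maps
(`A·sin(2π(f_x x + f_y y) + ψ)`, amplitude uniform in [0, 2π] rad,
frequencies uniform in [0, 2] cycles/FOV — ranges exposed in
`SinusoidalPhaseParams` since no canonical values exist) for the generated
ones.

## Undersampling and reconstruction

The mask samples every 4th phase-encode line (offset 0 — the offset is
unstated in the usual protocol, fixed here for determinism) plus a
contiguous centred calibration block of 26 lines (`[n/2−13, n/2+13)`);
at 320 lines this is 99 sampled lines, acceleration 3.23.

The reconstruction model is a size-parameterized end-to-end variational
network: per cascade,

```
k ← k − w·mask·(k − k₀) − FFT( CSM · CNN( Σ conj(CSM)·IFFT(k) ) )
```

with a learnable data-consistency weight `w` per cascade and a small
2-channel CNN regularizer (zero-initialized output: an untrained cascade
is pure data consistency, so the untrained network reproduces the
zero-filled reconstruction and training can only improve on it).
Sensitivities come from the calibration-region estimator applied to the
masked data, refined by a small residual CNN and RSS-renormalized inside
the graph. The default instance is deliberately small (4 cascades, 16
channels): the structure — unrolled data consistency, learned image-space
regularization, learned sensitivity refinement — is the point, not
benchmark capacity. Training minimizes `1 − mSSIM` (differentiable SSIM,
11×11 Gaussian window σ=1.5) against the RSS of the fully sampled slice,
with Adam at lr 1e-3.

Augmentation acts in the image domain on every coil image and the ground
truth identically (k-space is regenerated afterwards, which keeps the
geometric semantics exact and commutes with RSS for the discrete
subgroup): integer translation ±8 px, 90° rotations, mirroring,
continuous rotation ±10°, zoom 90–110%, sub-pixel translation ±16 px,
each independently enabled with probability 0.5. Continuous transforms use
bilinear interpolation with zero padding applied separately to real and
imaginary parts.

## Metrics and experiment protocol

MAE, RMSE and mSSIM are computed per slice and averaged per subject;
mSSIM uses the standard 11×11 Gaussian window, σ=1.5, K1=0.01, K2=0.03,
dynamic range set to the maximum of the ground-truth volume (it matches an
independent reference implementation to <1e-6). Paired t-tests pair
subjects across experiments; zero-variance (or rounding-level-variance)
differences are flagged degenerate rather than producing meaningless
statistics. No multiple-testing correction is applied; the report notes
this. Repeated runs are summarized by mean ± sd, and the run with the best
validation mSSIM is selected for comparisons (ties: lowest run id).

The grid runner trains one network per (mode × training size ×
repetition) cell and is bitwise reproducible from its master seed.

## Phantom fixtures

Phantoms provide exact ground truth for every factor of the signal model:
overlapping random ellipses confined to a central disc (so the 20×20 image
corners are exactly signal-free — the noise-estimation contract), a
low-order polynomial + single-sinusoid phase with a bounded per-pixel
step (default 0.5 rad), Gaussian sensitivity lobes around the perimeter
with per-coil linear phase ramps and global unit RSS, and coil-correlated
noise (σ=0.02, pairwise correlation 0.3). Coil 0 is kept real-positive,
which pins the phase convention and makes estimated maps directly
comparable to the ground truth. Defaults (64×64, 4 coils) keep the full
suite within minutes on one CPU; 320×320/16-coil phantoms mirror the
full-scale geometry when needed. Split rounding: validation and test
counts are floored, the remainder goes to train.

What the phantoms do **not** emulate: anatomical texture, B0-induced
phase structure, relaxation or post-processing effects (ringing filters,
quantization, background thresholding of stored magnitudes). Passing
phantom tests therefore demonstrates the correctness of the machinery —
decomposition, generation, synthesis, training — not that generated maps
match the statistics of clinical phase/sensitivity distributions.

## Problem sizes

Smoke-training sizes used by the tests and the acceptance script — chosen
so the complete pipeline (two generative models, super-resolution, and a
reconstruction network) exercises every code path at desk scale: AAE 500
steps / batch 8 on 40 slices at 16×16; super-resolution 300 steps on 20
decomposition-derived maps at 64×64; variational network 300 steps at
64×64 with 4 coils; the grid demonstration at 32×32 with 2 coils. The
full-scale protocol (1000 epochs × 200 batches, 320×320, 16 coils,
5 repetitions) is reachable through the same configuration objects.

## Known limitations

- Fixed operating grid per trained model (resolution is configurable but
  not variable within one model).
- The AAE latent capacity (4) bounds the map variability it can express;
  held-out regeneration is approximate by design.
- The sensitivity estimator is a calibration-region low-pass method; it is
  not an eigen-decomposition (ESPIRiT-style) estimator and degrades when
  the calibration block is very narrow.
- 2D Cartesian only; no non-Cartesian trajectories, no through-slice
  modelling, no DICOM/ISMRMRD ingestion.
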