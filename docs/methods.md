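# Methods

## The problem

Low-field MRI scanners (tens of mT) trade signal-to-noise ratio for cost and
portability. A shorter k-space sweep yields a lower-resolution image, so a
practical route to faster, cheaper scanning is to acquire a noisy 64×64 image
and restore a 128×128 image computationally. This package implements that
pipeline end to end: an acquisition-consistent degradation simulator, a dense
convolutional super-resolution network trained on simulated pairs, and the
classical zero-filling reconstruction it is compared against.

## Degradation model

MR acquisition measures k-space, so down-sampling is modelled there rather
than by blurring and decimating in image space:

    y = | F_LR^{-1} ( D F_HR x + n ) |

* `F_HR`, `F_LR^{-1}` — centered orthonormal 2D FFTs on the 128×128 and
  64×64 grids. DC sits at index `(N//2, N//2)`; Parseval holds exactly.
* `D` — the centered half-open crop window `[N/2 − n/2, N/2 + n/2)`:
  frequencies `−n/2 … n/2−1` are kept (asymmetric Nyquist handling,
  consistent with the DC-at-`⌊N/2⌋` convention).
* A rescaling factor `sqrt(h·w / (H·W))` is applied after cropping (its
  inverse after padding) so a noise-free constant image maps to the same
  constant at every grid size. Without a stated convention this is the only
  contract that makes LR/HR intensities directly comparable, and it is
  testable (constants are exact fixed points).
* `n` — circular complex Gaussian noise, real and imaginary parts each
  `N(0, σ²/2)`. The noise level is parameterized relative to the signal:
  `σ = ρ · RMS(|cropped coefficients|)`, with `ρ` drawn uniformly per image
  from `noise_rho_range` (default 0.02–0.20). The default range is a
  configurable stand-in for unpublished scanner noise levels, not a constant.
* The complex-to-real step takes the magnitude, matching how MR images are
  displayed; in the image domain this produces the characteristic
  Rician-like noise floor.

Zero-filling (`zero_fill_sr`) embeds the LR k-space in a 128×128 zero grid
and inverse transforms; it is the classical interpolation baseline. Images
whose spectrum fits inside the retained block are exact fixed points of
degrade-then-zero-fill (to float rounding, ~1e−16), which the tests exploit
as an oracle.

## Network

SRDenseNet-style architecture, fully convolutional, upsampling factor 2:

* initial 3×3 convolution → 16 feature maps;
* 8 dense blocks of 8 convolutional layers (3×3, growth 16), each block
  contributing 128 new maps;
* "All"-style skip connections: the initial features and every previous
  block's output are concatenated into each block's input and into the
  bottleneck;
* 1×1 bottleneck to 256 maps (input width 16 + 8·128 = 1040);
* one transpose convolution, 3×3, stride 2, 256 → 256;
* final 3×3 convolution to one channel; ReLU everywhere except the output.

Prose descriptions of this family under-determine several wiring choices.
They are explicit `ModelConfig` knobs, and `calibrate_wiring` enumerates a
grid of 480 variants against a target trainable-parameter count:

| knob | meaning | calibrated default |
|---|---|---|
| `initial_conv_out` | width of the low-level feature conv (or none) | 16 |
| `include_initial_in_concat` | initial features join skip/bottleneck concat | yes |
| `cumulative_block_inputs` | skips feed every later block vs. bottleneck only | yes |
| `dense_include_block_input` | dense layers ≥2 re-see the block input | no |
| `deconv_kernel` | transpose-convolution kernel | 3 |
| `deconv_out` | transpose-convolution width | 256 |
| `biases` | biases on every layer | yes |

With these defaults the analytic per-layer count `Σ k²·c_in·c_out + c_out`
equals **1,910,689** exactly, and building the network and counting scalars
by introspection agrees. The load-bearing reading is
`dense_include_block_input = False`: inside a block, layer *j* ≥ 2 receives
only the concatenated *outputs* of the preceding layers of that block, while
the (wide) block input is consumed by layer 1 alone. Re-concatenating the
block input everywhere, with the same remaining knobs, gives ~4.8M
parameters; other straightforward readings land between 2.0M and 2.4M.

Weights are He-uniform (fan-in) initialized, seed-controlled. There is no
normalization layer anywhere, so the receptive field is strictly local — a
property the tests check directly.

The network, backpropagation and Adam are implemented in numpy (NHWC,
float32). Convolutions are computed as one fat GEMM per layer followed by
per-offset shift-adds; the transpose convolution is the exact adjoint of the
stride-2 SAME convolution (adjointness is unit-tested, and all gradients are
checked against central finite differences). This keeps the wide
concatenated inputs streaming through BLAS exactly once per pass, which is
what makes a ~2M-parameter network usable on one CPU.

## Training

Patch-based supervision: 32×32 HR patches against 16×16 LR patches cut at
halved coordinates from the *full* degraded LR image. Degrading a 32×32
patch in its own k-space would be a different operator (periodic-boundary
leakage), so patches are never re-degraded; the residual patch-boundary
effect of the baseline reconstruction is quantified in the tests. Patch
origins are uniform random even pixels, sampled with replacement; HR/LR
pairs are split at the phantom level before any patch is cut, so no image
leaks across train/val/test.

Objectives: MSE (default), ℓ1, and HFEN — the relative ℓ2 norm of the
Laplacian-of-Gaussian filtered difference (15×15 kernel, σ = 1.5,
mean-subtracted so constants are annihilated exactly; symmetric padding,
with the exact adjoint used for its gradient). Optimization is Adam at
learning rate 1e−3, batch 20, β = (0.9, 0.999), ε = 1e−8, no schedule, no
weight decay, no augmentation. The returned model is the epoch with the
smallest validation loss (earliest on ties); a fixed epoch budget with
post-hoc selection and early stopping via `patience` are both expressible.

## Synthetic phantoms

The generator emulates piecewise-smooth brain-like anatomy: a head ellipse
kept inside the frame (background exactly zero), 3–8 inner ellipses painted
with intensity levels in [0.15, 1], Gaussian-smoothed boundaries
(σ = 1 px), a low-frequency multiplicative texture (amplitude 0.15), and
per-image max normalization. Intensity-level diversity stands in for the
contrast variety (T1/T2/FLAIR) of a clinical database; no relaxation-time
physics, partial-volume effects, or anatomical topology are modelled.
Consequently, passing tests demonstrate that the pipeline inverts its own
acquisition model on piecewise-smooth images — they do not certify clinical
image quality, reconstruction of pathology, or robustness to scanner
artifacts not present in the simulator.

## Evaluation

PSNR (`10·log10(range²/MSE)`, +∞ sentinel for bit-identical images) and
SSIM (Gaussian window 11×11, σ = 1.5, K₁ = 0.01, K₂ = 0.03). `data_range`
is fixed at 1.0 under the per-image-max normalization contract and recorded
in every report. Network outputs are clamped to [0, 1] only at
export/metric time — raw outputs are never clamped inside the pipeline.
Aggregation is the unweighted mean ± sd across images, with per-image rows
always retained.

## Problem sizes and numerical choices

* Desk-scale end-to-end check: 500 phantom pairs (400/50/50 split), 2,000
  training patches, a fixed budget of 200 Adam steps (2 epochs × 100 steps,
  batch 20), evaluation on the 50 held-out pairs. At this budget the
  network's mean PSNR and SSIM already exceed zero-filling's by a wide
  margin (≈ +9 dB and ≈ +0.5 SSIM at seed 2026); larger budgets widen the
  gap. These sizes are the package's own desk-scale choice — the reference
  protocol (tens of thousands of database slices, 190k patches, 74 epochs on
  a GPU) is emulated in procedure, not in scale.
* FFT round-trips are exact to 1e−10 by construction (orthonormal numpy
  FFTs); oracle comparisons run an independent O(N⁴) direct-sum DFT on
  grids ≤ 16×16.
* Degenerate inputs: non-finite images, undersized grids (< 8 px for
  operators, < 16 px for the network), invalid crops/pads, negative noise
  levels and empty datasets raise `ValueError` at the API boundary.
* Ties in best-epoch selection break to the earliest epoch. Training aborts
  with a diagnostic on a non-finite loss.
* Determinism: a single master seed fans out to named substreams (phantom
  geometry, noise, initialization, shuffling, patch sampling) via
  `SeedSequence`, so any stage can be rerun independently and
  bit-identically on the same device.

## Known limitations

* Pure-numpy training is single-device and CPU-bound; wall-clock cost is
  roughly 1.5–2 s per batch-20 step for the full calibrated network.
* The simulator models Cartesian full-plane k-space truncation only — no
  partial Fourier, non-Cartesian trajectories, coil combination, or B0
  effects.
* The phantom generator's realism gap (above) means measured PSNR/SSIM gains
  quantify the method on synthetic anatomy, not on clinical data.
* Only the ×2 upsampling factor is supported (single stride-2 transpose
  convolution).
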