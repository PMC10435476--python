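# Methods

## The problem

Photoacoustic microscopy (PAM) trades resolution against depth through
its focusing mechanism.  Optical-resolution PAM (OR-PAM) focuses the
excitation laser to a ~12 um lateral spot but loses the signal beyond
roughly 1 mm of tissue; acoustic-resolution PAM (AR-PAM) focuses the
received ultrasound instead, reaching ~1.9 mm (and several millimetres
for a low-frequency "deep" variant at 590 um lateral / 150 um axial) at
the cost of ~85 um lateral resolution.  Both modes share the transducer,
so axial resolution (~27 um) is common.  `pamgan` learns the mapping from
AR-like b-scans to OR-like b-scans with two adversarial strategies and
provides the simulation and measurement scaffolding to test whether the
mapping genuinely restores resolution rather than hallucinating it.

## Data model and conventions

A scan is a non-negative amplitude volume indexed `(y, x, z)` — slow
scan, fast/lateral scan, depth — so a b-scan is an `(x, z)` plane and the
en-face maximum-amplitude projection (MAP) is the per-`(y, x)` depth
maximum.  Argmax ties in the MAP resolve to the shallowest depth, which
is deterministic and physically conservative.  On disk, volumes are
multi-page TIFF (uint8; page = slow-scan position, rows = depth) or HDF5
(float, lossless, with pitch/modality attributes).  Amplitudes are
normalized once per volume by the global maximum: per-slice scaling would
destroy the depth-attenuation signature that the networks are supposed to
learn.

Patch tiling is deterministic raster order with edge tiles shifted inward
so every tile holds real data (zero padding is used only when a b-scan is
smaller than one tile); disabling random jitter keeps AR/OR tiles
co-registered.  8-bit conversion rounds half up, making cross-platform
tests bit-exact.

A-line filtering is a zero-phase (forward-backward) Butterworth bandpass,
order 4, followed by the analytic-signal envelope.  Zero-phase filtering
is chosen because any group delay would shift the depth axis and corrupt
AR/OR pairing.  Default bands are 10-90 MHz for the 50 MHz dual-system
transducer and 1-9 MHz for the 5 MHz deep system (+/-80% fractional
bandwidth, a standard transducer assumption; the band edges are
configurable because the hardware's true band is not published).  Whether
filtering precedes or follows envelope detection is configurable; the
filter-then-envelope order is canonical here, as in conventional
ultrasound processing.

## Forward simulator

No public AR/OR dataset exists, so training and evaluation run on a
simulator with known ground truth.  The forward model is intentionally
minimal:

* **Geometry.** Hair phantoms: straight cylinders with linearly
  increasing centreline depth (the classic resolution phantom), axis
  selectable between the fast and slow scan directions.  Vessel phantoms:
  seeded random branching tubes with smoothly meandering centrelines,
  depth-damped vertical drift, and diameters that shrink at branches.
* **PSF.** Separable Gaussian: isotropic 2D lateral x 1D axial.  A
  Gaussian is the natural choice given that system resolutions are
  reported as Gaussian-fit FWHMs.  The lateral FWHM grows linearly
  outside the depth of focus,
  `FWHM(z) = FWHM_f * max(1, 1 + g * max(0, |z - z_f| - DOF/2))`,
  applied slice-by-slice in depth (shift-variant blur in z only), which
  captures out-of-focus degradation at desk-scale cost.
* **Sensitivity.** Amplitude decays as `exp(-z / L)` with attenuation
  length `L` a free parameter (default 1500 um; the real decay law is not
  published, so no test depends on its exact value), plus a hard
  visibility cutoff: 1000 um (OR), 1900 um (AR), 5000 um (deep AR).
* **Noise.** Additive Gaussian noise (default sigma 0.01 of full scale)
  and salt-and-pepper corruption, the latter by default only on the OR
  channel where it is observed in practice.

All stochastic steps are pure functions of (inputs, seed).  Defaults for
the dual system: OR (12 um lateral, 27 axial, focus 500 um, DOF 400 um),
AR (85, 27, 500, 1500), voxel pitch 5 um lateral / 10 um depth.

What the simulator does **not** model: wave propagation and speckle,
fluence variation, motion, registration error between modes, and the
heterogeneous absorber spectrum of real tissue.  Passing the recovery
benchmark therefore shows that the training/enhancement machinery can
invert a known, well-posed degradation — not that it reaches the
performance of full-scale networks trained on real co-registered scans.

## Networks and training

The generator is the standard residual translation network: 7x7 stem,
two strided-convolution downsamples, nine residual blocks (full scale),
a mirrored decoder, and a tanh output rescaled to [0, 1] to match
8-bit-normalized patches.  Decoder upsampling is nearest-neighbour
resize followed by convolution rather than a transposed convolution;
the shape contract is identical and resize-convolution avoids
checkerboard artifacts.  Normalization is per-instance (stable at batch
size 1); padding is reflective.  The discriminator is a patch
discriminator — stacked strided 4x4 convolutions emitting a sigmoid
decision map (a 70x70-receptive-field configuration maps 256x256 input
to a 30x30 grid); a `global_scalar` mode mean-pools the map to a single
1x1 decision.  Whether the original design kept the map or reduced it is
ambiguous, so both modes exist and the loss averages the map either way.
The paired discriminator is conditioned by channel-concatenating the
source AR patch with the candidate; cycle discriminators see the
candidate alone.

Because no deep-learning framework ships with the package's environment,
`pamgan.nn` is a self-contained ~400-line tensor core: im2col/BLAS
convolutions with exact reflect-padding gradients, tape-based backprop
(a network can appear multiple times in one objective, as cycle training
requires), instance/batch norm, Adam, and BCE/least-squares/L1 losses.
Gradients of every layer are verified against central differences in the
test suite.  Compute is float32.

Objectives.  Paired: `adv + w_L1 * ||O - G(A)||_1` with the
conditional-adversarial term; unpaired: adversarial terms in both
directions plus `w_cyc * (||Gb(G(A)) - A||_1 + ||G(Gb(O)) - O||_1)`.
The published weight statement ("0.01") is read as the adversarial-to-L1
ratio, so the default profile is `w_L1 = 100` with unit adversarial
weight; the literal inverse profile is one config line away.  Defaults
follow the cited model families where the source is silent: Adam with
betas (0.5, 0.999), batch size 1, initial learning rate 2e-4 halved at
epochs 100 and 150 of 200 (the decay factor is published, its timing is
not), 1:1 discriminator/generator steps.  Training is a pure function of
(data, specs, config seed); checkpoints embed specs, seeds and history
and restore bit-identically.

## Inference

Whole volumes are enhanced slice-wise (no cross-b-scan state): tiles are
extracted with the training geometry but a half-patch stride, translated,
and stitched with average blending, which removes seam artifacts; with an
identity generator the stitcher provably reproduces the input exactly,
including inward-shifted edge tiles.  No thresholding or filtering is
applied after generation — any denoising behaviour must come from the
learned mapping itself.

## Quality metrics

`SNR(dB) = 10 log10(P_s / P_n)` with P the mean squared amplitude over an
explicit rectangular ROI; `CNR(dB) = 10 log10((mu_s - mu_b) / sigma_b)`
exactly as printed (not the 20-log amplitude convention some PA work
uses).  SSIM is the standard luminance-contrast-structure index over
7x7 uniform windows with K1 = 0.01, K2 = 0.03 and unbiased covariance,
cross-checked in the tests against an independent implementation to
1e-6.  ROIs are always caller input and are echoed into the report —
automatic ROI guessing would silently change the measurement.  Lateral
and axial resolution are reported as the FWHM `2 sqrt(2 ln 2) sigma` of a
least-squares Gaussian fit (moment initialization) to an axis-aligned
line profile.  A complex-wavelet SSIM variant (FFT Gabor bank, single
scale) is included as an optional, shift-tolerant metric but takes no
part in acceptance.

## The desk-scale recovery benchmark

`pamgan.benchmark` freezes the study conditions under which the central
claim is tested on one CPU in minutes (all sizes chosen once, as the
package's own protocol):

* 10 um isotropic voxels; AR lateral FWHM 80 um = 8 px vs OR 20 um =
  2 px; shared 27 um axial; Gaussian noise sigma 0.01 in both domains.
  Salt-and-pepper is deliberately absent here: an unpaired domain
  discriminator otherwise rewards hallucinated speckle (a known
  pathology of cycle-consistent translation), which would contaminate a
  benchmark aimed at resolution recovery.
* 3 training volumes of 64 vessel-phantom b-scans (192 pairs of 64x64
  patches) + 1 held-out volume; a held-out 40 um tube along the slow
  axis at focal depth as the resolution probe (40 um = 4 px keeps the
  Gaussian fit well-conditioned; a 2 px tube leaves it nearly degenerate).
* compact networks (2 residual blocks, 8 base filters, 1 downsample;
  2-layer discriminator) and short schedules: paired 25 epochs, unpaired
  30 epochs, lr 1e-3, batch 4, least-squares adversarial loss in both
  profiles.

A trained model passes when, on held-out data, (a) its outputs are closer
to the OR targets in L1 than the raw AR inputs, (b) the probe tube's
fitted FWHM is closer to the OR value than to the AR value, and (c) SSIM
against the noise-free truth exceeds the AR baseline.  Both regimes pass
all three; representative numbers appear in the README's worked example.

## Numerical notes and limitations

* Gaussian blur sigmas below 0.05 px are treated as identity (the
  delta-kernel limit), making the no-blur simulator limit exact.
* The Gaussian fitter requires >= 5 samples and a non-constant profile;
  fits are bounded (positive amplitude and sigma) and report RMSE.
  Under-sampled peaks (2-3 px) fit but with little meaning — hence the
  4 px benchmark probe.
* CNR is undefined when the signal mean does not exceed the background
  mean; the metric raises rather than returning a complex/negative-log
  value, and the comparison table records it as missing.
* Bit-level reproducibility holds on a fixed platform (BLAS determinism
  is platform-wide, not cross-platform).
* Training stability at desk scale is seed-robust in the margins tested,
  but adversarial optimization remains noisy by nature; the benchmark
  asserts orderings, never absolute loss values.
* The uint8 TIFF path quantizes float volumes (documented, tagged in the
  file); HDF5 is the lossless route.
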