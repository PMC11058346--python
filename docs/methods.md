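# Methods

## Problem setting

A single OCT B-scan is modeled as a clean reflectivity image `y` in `[0,1]`
corrupted by fully-developed multiplicative speckle and detector noise:

```
y_noisy = clip(y * G + eps + stripes, 0, 1)
```

with `G` i.i.d. per-pixel gamma noise of shape `k` and scale `1/k`
(mean 1, variance `1/k`; `k` is the *number of looks* — larger `k`, less
speckle), `eps` zero-mean gaussian read-out noise, and optional bright
full-width single-row stripe artifacts. The gamma intensity model is the
standard choice for fully developed speckle and makes the ENL statistic
directly interpretable. Note that the final clip truncates the upper
speckle tail: for a constant 0.5 image at `k = 4` the exact noisy mean is
`0.5 * P(5, 8) + Q(4, 8) ~= 0.4926`, not 0.5; tests assert this analytic
value. The raw field `G` is exposed separately (`speckle_field`) so its
moments can be checked unclipped.

Images are floats in `[0,1]` throughout; file bit depth (8/16-bit PNG/TIFF)
is purely an I/O concern, and the PSNR/SSIM dynamic range is `L = 1`.

## Synthetic phantoms

The generator emulates retinal/dental cross-sections:

* `n` horizontal tissue layers between strictly increasing boundary rows;
  each boundary undulates sinusoidally across the scan (seeded phase,
  0.5–1.5 cycles, amplitude `boundary_jitter`, clamped so boundaries never
  re-order). Sinusoidal rather than per-column random undulation keeps the
  boundaries smooth like real retinal layers.
* Inside each layer the intensity falls by `layer_gradient` (default 4%)
  from top to bottom — a depth-attenuation ramp — and is modulated by a
  smooth seeded low-frequency texture field (`texture_amplitude`, default
  5%, 3–8 cycles per image axis). The texture matters beyond realism: with
  perfectly uniform layers the clean reference has `sigma_s ~ 0.006` and a
  CNR near 21 dB that *no* smoothing network can reach, so the contrast
  term of the loss never equilibrates. With texture the clean CNR is
  ~17 dB, the same order as reported for real retinal references
  (~14 dB), and attainable.
* The default study conditions (`generate_pairs`): 64x64 phantoms, two
  layers (surface at rows 18–24, a 19–22 px bright layer of reflectivity
  0.55–0.9 over dimmer tissue 0.35–0.55), background level 0–0.04, jitter
  1–2 px, speckle at `k = 4`, additive sigma 0.02, a bright stripe artifact
  in 30% of images, and centered 12x12 signal/background ROI boxes placed
  clear of the boundaries. `k = 4` is heavy speckle, typical of raw
  (unaveraged) B-scans; geometry scales proportionally for other image
  sizes.

What the phantoms do **not** model: coherent PSF correlations (speckle is
i.i.d. per pixel), depth-dependent attenuation of the beam itself, lesion
morphology, or motion artifacts. Passing tests therefore show the pipeline
recovers piecewise-smooth layered scenes from multiplicative noise — not
that it reaches any particular quality on clinical data.

## Architecture

Patch encoder (attention gate). The image is tiled into `P x P` patches
(row-major, edge-padded to a multiple of `P` when needed) and, in parallel,
overlapping query boxes of the same size at stride `P/2`. Two embedding
towers (a learned `P^2 -> P^2` linear map, two 3x3 stride-3 same-padded
convolutions with 32 and 64 filters, flatten, linear projection to `D`)
embed patches and query boxes separately — the towers are *not* shared by
default (`shared_embedder` switches this). Patch `i` is scored against its
spatially nearest query box, `s = softmax_i(q_i . k_i / (sqrt(D) * T))`,
and its embedding is scaled by the gate `g_i = clip(N * s_i, 0, 1)` — 1 for
a featureless image, and a soft, almost-everywhere-differentiable
realization of hard background thresholding otherwise. The `1/sqrt(D)`
scaling is standard attention practice for numerical stability. With the
gate ablated away, a plain linear `P^2 -> D` patch embedding is used.

Encoder. A learned `N x D` positional table is added (no class token — a
reconstruction model has no classification head, so the token would be
dead weight), then `L` pre-norm transformer blocks
(`z' = MSA(LN(z)) + z`, `z = MLP(LN(z')) + z'`, heads concatenated and
projected, GELU MLP of width `2D` by default), then a final LN + MLP head.
Full-scale defaults follow the reference settings: `L = 8`, 8 heads,
`P = 32`; `mlp_hidden = 2D` is this package's choice (the width is not
specified upstream).

Decoder. Tokens are layer-normalized, reshaped onto the patch grid, and
passed through configurable (nearest-upsample, 3x3 conv) stages whose
upsample factors must multiply to `P`; default three stages with filters
(64, 32, 1). The final stage is **linear**, offset by +0.5 (so a
zero-initialized network outputs mid-gray), with no squashing; inference
clips to `[0, 1]`. This follows standard denoising-network practice
(DnCNN, SwinIR): a saturating output was tried first and is a one-way
ratchet on OCT-dark backgrounds — early contrast-term pressure (or even
plain MSE under Adam momentum) pushes the near-black background deep into
the sigmoid tail, where the vanished gradient prevents any recovery, the
background pins at exactly 0, and ENL collapses. With the linear head the
background returns to the clean level once the contrast gap closes.

## Loss

`L = L_MSE + L_diff + L_CNR + L_PSNR`, each term non-negative and zero at a
perfect reconstruction:

* `L_MSE`: mean squared pixel error.
* `L_diff = 1 - SSIM(pred, clean)` with the *global-statistics* SSIM (one
  window covering the image, stabilizers `c1 = (0.01 L)^2`,
  `c2 = (0.03 L)^2`) — the same form the evaluation reports, so loss and
  metrics agree. A windowed mean-SSIM is available but not used by default.
* `L_CNR = clip(|CNR(clean) - CNR(pred)| / 100, 0, 1)` on the pair's ROI
  boxes. As printed upstream the term reads `1 - gap/100`, which equals 1
  at equality — treated as a sign typo (the prose calls it a normalized
  coefficient in (0,1)); a `literal_paper_form` switch reproduces the
  printed formula for audit. Inside the differentiable CNR both the
  contrast and the pooled std are floored at `1e-3` (below one 8-bit gray
  level): this keeps the dB logarithm and its gradient bounded on arbitrary
  network output — without the floor the `1/sigma^2` gradient reaches
  `1e12` on near-flat regions and destroys training.
* `L_PSNR = clip((50 - PSNR(pred, clean)) / 100, 0, 1)`. PSNR of a perfect
  output is infinite, so a 50 dB ceiling (an MSE floor of `1e-5`) caps the
  reference; the term is 0 once the reconstruction reaches 50 dB.
* A degenerate clean-image ROI (flat boxes, inverted contrast) disables
  `L_CNR` for that image with a logged warning instead of aborting a batch.
* CNR/PSNR terms are computed per image and averaged over the batch.

Ablation variants: plain MSE, MAE, and pixelwise binary cross-entropy with
predictions clipped to `[1e-7, 1 - 1e-7]`.

## Training

Adam (AdamW selectable) at learning rate `5e-4`, batch 4 — the reference's
leading settings — with two standard stabilizers added after observing
divergence at this rate on the smoke scale: a linear learning-rate warmup
over the first 60 steps and a global gradient-norm clip at 1.0. Batches
are seeded shuffles; the best-on-validation (composite/variant loss)
parameters are kept. Training is single-threaded float64 and bit-
reproducible given the seed. Per-epoch loss components go to a CSV log;
checkpoints are a single `.npz` holding every parameter plus the JSON
config, and reload bit-identically.

## Smoke scale

The end-to-end tests and the acceptance script run a scaled-down surrogate
of the full configuration (which targets GPU-scale training): 64x64
phantoms, `P = 8`, `D = 32`, depth 2, 4 heads, decoder (32, 16, 1) with 2x
upsampling per stage, 200 pairs split 60:10:30, batch 4, lr `5e-4`,
16 epochs — about 25 s per run on one CPU. At this scale the denoiser
gains ~9–11 dB PSNR and ~0.18 SSIM on held-out phantoms, lifts CNR from
~4 to ~17 dB, and raises ENL by one to two orders of magnitude.

## Numerical and design notes

* Population (divisor `n`) statistics everywhere in ROI moments; all dB
  logarithms are base 10.
* ENL follows the reported `mu_b^2 / sigma_s^2` form by default (the
  background-mean / signal-std mix); `enl_convention="homogeneous"` gives
  the textbook `mu^2/sigma^2` over the background box alone. Degenerate
  metric inputs (flat ROI, zero MSE) return flagged `inf` sentinels rather
  than raising, so one flat image cannot abort a batch evaluation; CNR
  with inverted contrast raises a typed error.
* "Enlarge" in the augmentation family is a 1.25x central zoom-crop
  (factor configurable); the 7-member family is identity, three rotations,
  two flips, zoom. The same transform is applied to images and ROI boxes;
  a box the zoom-crop pushes out of frame drops the pair's ROIs with a
  warning.
* Dataset splitting floors the train and validation sizes and gives the
  remainder to test (n=10 -> 6/1/3, n=16 -> 9/1/6). ROI boxes are 0-based,
  half-open `{row, col, height, width}`.
* Images whose sides are not multiples of `P` are edge-replicated (never
  cropped) before patching, and the padding is recorded so re-assembly is
  lossless.
* The sliding-box query stride `P/2` requires an even patch size.
* The autodiff engine is float64 and validated against central finite
  differences for every op class, including both convolution backward
  paths (stride-1 matmul and strided scatter).

## Known limitations

* The smoke scale is a surrogate: absolute dB values on clinical OCT data
  are out of reach without the original datasets and GPU-scale training.
* Because the phantom references are *exact* clean images and the noise is
  i.i.d., minimizing MSE is already the PSNR-optimal training strategy; in
  the ablation harness the composite loss beats the MAE and BCE variants on
  held-out PSNR across seeds and matches plain MSE only on average
  (within a few tenths of a dB, per-seed a coin flip). The composite
  loss's PSNR advantage on real OCT data rests on the imperfect
  (registered/averaged or thresholded) clean references used there, which
  exact synthetic targets cannot emulate.
* Global-statistics SSIM saturates high on piecewise-constant phantoms
  (noisy baselines already score ~0.8).
* The attention gate's benefit is reported by the ablation harness, not
  asserted, mirroring the mixed direction reported upstream across
  datasets.
* i.i.d. speckle means there are no spatial noise correlations for the
  network to exploit or be confused by.
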