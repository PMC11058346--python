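# tear-oct

Speckle denoising of optical coherence tomography (OCT) B-scans with TEAR —
a **t**ransformer-**e**nhanced **a**utoencoder **r**endering network — plus
everything needed to train and evaluate it without any external data:
a synthetic layered-phantom generator, a composite quality-aware loss, and
ROI-based image-quality metrics.

OCT images are formed from low-coherence interferometry, so they carry
multiplicative speckle: granular noise whose variance scales as `1/k` with
the number of looks `k`. Speckle obscures the thin tissue layers
(retinal strata, dental enamel junctions) that clinicians read. TEAR
denoises B-scans by

1. splitting the image into non-overlapping `P x P` patches and scoring each
   patch against an overlapping *sliding-box* query window through two small
   convolutional embedding towers — an **attention gate** that suppresses
   background patches (`g_i = clip(N * softmax_i, 0, 1)`),
2. encoding the gated patch tokens with a ViT encoder — `L` pre-norm
   transformer blocks, `z'_l = MSA(LN(z_{l-1})) + z_{l-1}`,
   `z_l = MLP(LN(z'_l)) + z'_l` with GELU MLPs — and
3. decoding the tokens back to a full-size image through
   (upsample, 3x3 conv) stages.

Training minimizes a composite loss over noisy/clean pairs

```
L = L_MSE + L_diff + L_CNR + L_PSNR
L_diff = 1 - SSIM(pred, clean)
L_CNR  = clip(|CNR(clean) - CNR(pred)| / 100, 0, 1)
L_PSNR = clip((50 dB - PSNR(pred, clean)) / 100, 0, 1)
```

where CNR (contrast-to-noise ratio, dB) is measured on a signal box and a
background box per image, so the loss rewards pixel fidelity, structural
similarity, contrast preservation/hard background thresholding, and overall
signal restoration at once. Single-term MSE / MAE / BCE variants are kept
for ablations. Everything runs on a small self-contained numpy
reverse-mode autodiff engine — no GPU or deep-learning framework required.

Evaluation uses the standard OCT quartet: **SSIM**, **PSNR**
(`10 log10(L^2/MSE)`), **CNR** (`10 log10((mu_s - mu_b)/sqrt(sig_s^2 + sig_b^2))`),
and **ENL** (`mu_b^2 / sigma_s^2`, a smoothness statistic; a homogeneous
`mu^2/sigma^2` convention is also available), plus the usual
accuracy/sensitivity/specificity/precision/F1 ratios for downstream
classification experiments.

## Worked example

```python
from tear.phantom import generate_pairs
from tear.dataio import split_dataset
from tear.pipeline import smoke_run_config, train

pairs = generate_pairs(200, seed=100)        # noisy/clean phantoms + ROIs
split = split_dataset(pairs, seed=100)       # 60:10:30
state, report = train(smoke_run_config(seed=0), split)
print(report.test_metrics.loc["mean"].round(3))
```

prints (held-out means over the 60 test phantoms):

```
ssim_noisy        0.796
psnr_noisy       14.289
cnr_noisy         3.924
enl_noisy         0.012
ssim_denoised     0.973
psnr_denoised    23.566
cnr_denoised     17.272
enl_denoised      0.300
```

i.e. the denoiser gains ~9 dB PSNR and ~0.18 SSIM over the raw speckled
input, raises ROI contrast from ~4 to ~17 dB, and smooths the image (higher
ENL). The same workflow is available from the shell:

```bash
tear generate --n 200 --out data/
tear train --data data/ --out run/ --epochs 16
tear denoise --ckpt run/model.npz --in data/ --out run/denoised/
tear evaluate --pred run/denoised/ --ref data/ --rois data/ --out report.csv
tear ablate --data data/ --out ablation.csv
```

## Synthetic phantoms

Real OCT training sets (registered noisy/clean retinal pairs, dental scans)
are not redistributable, so the `tear.phantom` module emulates their
structure: piecewise-bright horizontal tissue layers with smoothly
undulating boundaries over a dark background, a gentle axial attenuation
gradient and low-frequency reflectivity texture inside the tissue,
fully-developed multiplicative gamma speckle (`mean 1, variance 1/k`),
additive detector noise, and occasional bright horizontal stripe artifacts.
Signal/background ROI boxes are placed automatically clear of the layer
boundaries. All generation is a pure function of `(spec, seed)`.

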