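# canopyhsi

Hyperspectral canopy analysis and nutrient-stress classification for
terrestrial (proximal) crop imaging.

Factorial fertilization trials produce canopies whose reflectance spectra
differ only subtly between treatments: nitrogen starvation brightens the
green/red region (chlorosis) and darkens the near-infrared plateau,
phosphorus and potassium shift the plateau level and leaf-water
absorption.  `canopyhsi` covers the full path from raw cubes to per-pixel
treatment classification for this kind of study:

* **I/O and calibration** — ENVI raster reading/writing (BIL/BIP/BSQ),
  reference-panel reflectance calibration
  `rho(lambda) = Phi_r(lambda, t1) * rho_s(lambda) / Phi_i(lambda, t0)`,
  NDVI-threshold background masking, representative-spectrum extraction.
* **Simulation** — labeled synthetic scenes with 14 parameterized NPK
  treatment classes (coded A–N, e.g. F = N2P2K2 reference), built from
  vegetation endmembers with a green peak (550 nm), red valley (680 nm),
  logistic red edge, NIR plateau and 960 nm water dip, plus biological
  variability, sensor noise and water/soil backgrounds.
* **Characterization** — NDVI, PRI `(rho_531-rho_570)/(rho_531+rho_570)`,
  PSRI `(rho_680-rho_500)/rho_750`; band-wise mean/CV profiles;
  covariance PCA of spectra; t-SNE embedding.
* **SuperPCA** — superpixelwise PCA reduction: PC1 image → entropy-rate
  superpixel segmentation (native implementation; SLIC fallback) →
  per-segment top-B PCA bases → `S x S x B` patch extraction.
* **SHCFTT classifier** — a spectral–spatial CNN–transformer hybrid:
  three valid-mode 3-D convolutions (8/16/32 kernels of 3×3×7, 3×3×5,
  3×3×3), a 64-kernel 3×3 2-D convolution gated by CBAM
  (channel-then-spatial attention), a Gaussian-initialized feature
  tokenizer `T = softmax_positions(G W_a)^T G`, and a pre-norm
  transformer encoder block whose classification token feeds a linear
  softmax head.  Runs on the package's own numpy reverse-mode autodiff
  engine; no GPU or deep-learning framework required.
* **Evaluation** — OA / AA / Cohen's kappa from the confusion matrix,
  stratified 70/30 and 5/95 splits, 10-fold CV, a 7-case component
  ablation harness, and per-pixel classification maps.

## Worked example

```bash
python examples/05_train_shcftt.py
```

trains the default architecture under a stratified 70/30 split of pooled
single-treatment scenes (well-separated classes, 60 labeled pixels per
class) and prints:

```
train: n=588  OA 100.00%  AA 100.00%
test:  n=252  OA 100.00%  AA 100.00%  Kappa(x100) 100.00
```

i.e. every one of the 14 treatments is recovered on held-out pixels.  The
other scripts in `examples/` are one capability each: masking, index
tables, PCA/t-SNE characterization, SuperPCA patches, the small-sample
model comparison and ablation, and ENVI/calibration round trips.  A thin
CLI (`canopyhsi simulate|indices|train|evaluate|ablate`) wraps the same
functions for shell use.

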