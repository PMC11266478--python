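# Methods

## Problem setting

Proximal hyperspectral imaging of crop canopies under factorial NPK
fertilization yields cubes of per-pixel reflectance spectra (here: 204
bands over 400–1000 nm, the grid of a typical VNIR field camera).  The
scientific task is to decide, per pixel, which of 14 nutrient treatments
(one balanced reference plus N/P/K gradients and compound deficits,
lettered A–N) produced the imaged canopy.  Because real campaigns of this
kind are rarely public, the package ships a parametric simulator that
stands in for the field data; every accuracy quoted anywhere in this
repository is measured on that simulator, and the package's claims are
therefore about the method's behavior under the simulator's assumptions,
not about any particular field dataset.

## Reflectance calibration

Field reflectance is obtained against a near-Lambertian reference panel
(nominal reflectance factor ~0.99).  With panel radiance `Phi_i` taken at
`t0` and target radiance `Phi_r` at `t1`,

    rho_corr(lambda) = Phi_r(lambda, t1) * rho_s(lambda) / Phi_i(lambda, t0)

where `rho_s` corrects the panel's departure from a perfect reflector.
The implementation warns when `|t0 - t1|` exceeds 15 minutes, the usual
illumination-stability window.  Dark-current, geometric and atmospheric
corrections are out of scope (they normally happen in vendor software
before export).

## The scene simulator

An endmember (noiseless class spectrum) is

    rho(l) = clip( base + A_g * G(l; 550, w_g) - d_rv * G(l; 680, 25)
                   + P / (1 + exp(-(l - l_re)/w_re)) - d_w * G(l; 960, 45), 0, 1)

with a Gaussian green peak, Gaussian red valley, logistic red edge to a
NIR plateau and a leaf-water dip.  Defaults (base 0.08, A_g 0.06, w_g 35
nm, d_rv 0.05, l_re 710 nm, w_re 15 nm, P 0.45, d_w 0.05) give NDVI ~0.79
and a global maximum on the plateau.  Treatment offsets follow stress
physiology: per unit of N-level deviation from balanced, the green-peak
amplitude rises 0.012 and the plateau falls 0.020 (chlorosis and
mesophyll breakdown under N starvation); P shifts the plateau (0.012 per
level); K modulates the water-dip depth (0.010) and green-peak width
(2 nm).  A small seeded Gaussian jitter breaks symmetry between
treatments sharing level patterns.  All offsets scale with a single
`separability` knob; 0 makes all classes identical, 1 is the default
regime, and 2 is used as the "well-separated" regime in the recovery
experiments.

Pixels are `endmember * exp(sigma * N(0,1)) + N(0, noise_sd)` clipped to
[0, 1]: one multiplicative lognormal factor per pixel (canopy-brightness
variability, default sigma 0.05) and independent additive Gaussian sensor
noise per band (default sd 0.01).  Background pixels alternate two fixed
archetypes (water: monotone decreasing; soil: monotone increasing) and
carry label 0.  Two scene geometries exist: a multi-plot mosaic (grid or
Voronoi layout; used for segmentation and masking studies) and
single-treatment scenes — one plot over background per acquisition —
which mirror how proximal campaigns actually image one plot at a time and
are what the classification protocols pool.  What the simulator does
*not* model: radiative-transfer physics, BRDF, mixed border pixels,
illumination gradients within a scene, or spectrally structured noise.
Passing tests therefore demonstrate correctness and sensible behavior of
the pipeline, not field-level performance.

## SuperPCA

The cube's pixels are projected onto their first principal component; the
resulting grayscale image is segmented by entropy-rate superpixel
clustering (ERS): edges of a 4-neighbor lattice graph, weighted by a
Gaussian intensity similarity, are greedily added to maximize the random
walk's entropy rate plus a size-balancing term (both submodular, so a
lazy max-heap greedy is exact for the schedule) until K components
remain.  The balance weight defaults to 2x the mean initial entropy gain,
which empirically yields near-equal areas on featureless images while
preserving strong boundaries exactly; `connectivity=4` keeps every
segment 4-connected.  SLIC is available as a fallback
(`method="slic"`).

Each segment then receives its own top-B PCA basis (from the segment's
centered covariance; sign convention: each loading's largest-magnitude
entry is positive).  **The projection is applied to the raw, uncentered
pixels by default.**  Projecting centered pixels (available via
`center=True`) subtracts the segment's mean spectrum — which *is* the
class signature when an acquisition contains a single treatment — and
makes independently reduced scenes mutually uninformative; the uncentered
projection keeps the mean encoded and matches the behavior of the
reference SuperPCA lineage.  Segments smaller than B pixels fall back to
the global-image basis.  The number of superpixels should roughly match
the number of distinct spectral populations in the scene: the protocols
use K=4 for 70/30 runs and K=2 (vegetation vs background) for the
small-sample runs, where per-segment basis jitter is costlier than local
adaptation.

Patches of `S x S x B` (defaults S=13, B=30, chosen so the convolution
stack below stays shape-valid) are cut around every labeled pixel with
zero padding of width (S-1)/2 at image borders; each patch inherits its
center pixel's label.

## The SHCFTT classifier

Input: one patch, treated as a 1-channel 3-D volume (height, width,
spectral).

1. Three valid-mode stride-1 3-D convolutions with 8, 16, 32 kernels of
   3×3×7, 3×3×5, 3×3×3 (spatial × spatial × spectral), each followed by
   batch normalization and ReLU.  With S=13, B=30 the shapes run
   13→11→9→7 spatially and 30→24→20→18 spectrally; a shape ledger
   validates any (S, B) against the stack and names the offending layer
   on underflow.
2. The channel and spectral axes merge (32·18 = 576 planes) and one 3×3
   2-D convolution maps to 64 channels, followed by CBAM: channel
   attention from a shared two-layer MLP over global average- and
   max-pooled descriptors (reduction 16), then spatial attention from a
   7×7 same-padded convolution over the channelwise average/max maps,
   both sigmoid gates.
3. The 5×5×64 map flattens to G (25 positions × 64 channels) and the
   tokenizer forms w=4 semantic tokens `T = A^T G` with
   `A = softmax_over_positions(G W_a)`, `W_a` Gaussian-initialized.  Each
   attention column is a distribution over positions, so every token is a
   convex combination of feature rows.  (The softmax axis is over
   positions; the alternative reading — over tokens — would not make the
   columns semantic groups.)
4. A learnable classification token is prepended, learnable position
   embeddings added, and one pre-norm transformer encoder block applied:
   `x' = x + MSA(LN(x))`, `out = x' + MLP(LN(x'))`, with h=4 heads of
   dimension d_K=16 and an MLP of width 4z.  The multi-head output
   projection maps `h*d_K -> z` so the block preserves the sequence shape
   (a projection to w dimensions, sometimes written for this
   architecture, cannot).  The encoded classification token feeds a
   linear layer and softmax; argmax ties break to the lowest class id.

Everything runs on a small tape-based reverse-mode autodiff engine over
numpy (float32 compute; convolutions via a cached im2col GEMM with a
per-kernel-offset scatter for the input gradient).  Backprop is verified
against central finite differences, per-op and end-to-end (in float64
with step 1e-5; coarser steps are biased by ReLU curvature).

Training: Adam (lr 1e-3, batch 64, 100 epochs by default; seeded init and
shuffling make runs bit-reproducible), cross-entropy, dropout 0.1 in the
encoder.  The small-sample recipe (used whenever only tens of labels per
class exist) is lr 2e-3, batch 16, 150–200 epochs with cosine decay and
dropout 0 — small batches give enough optimizer steps, and the decay
removes the late-training instability that constant rates show at these
sample sizes.  Network trainers can standardize inputs per feature band
(stored with the model and in checkpoints); this is on for the 1-D CNN on
raw spectra and off for SuperPCA patches, whose natural scale decay is
itself informative — standardizing would re-amplify pure-noise
components.

Baselines: an RBF-kernel SVM (standardized inputs, small C/gamma grid
searched by CV inside the training split) and a 1-D CNN on per-pixel
spectra; a 3-D CNN on the same patches (the SHCFTT conv stack with a
global-average-pool head — the small-sample-friendly head — or optionally
a flatten+FC head).

## Evaluation

From the confusion matrix x (rows truth, columns prediction): overall
accuracy = trace/total; average accuracy = macro-averaged per-class
recall; Cohen's kappa = (p_o - p_e)/(1 - p_e) with p_e from row/column
marginals, reported ×100.  The (p_o, p_e) form is unit-tested to equal
the expanded ratio form algebraically.  Splits are stratified with
rounding to the nearest integer per class (70/30 and 5/95 protocols);
10-fold stratified CV is provided.  The sampling unit is the labeled
pixel, which matches the per-pixel classification framing but is
optimistic for generalization to new acquisitions because neighboring
patches overlap; `standard_protocol(scene_split=True)` trains and tests
on disjoint replicate scenes and is the recommended protocol for
generalization claims.  The no-signal control (separability 0) uses the
scene-level split precisely because with pixelwise splits a
high-capacity model can identify the acquisition (through scene-specific
noise and basis jitter) rather than the treatment.

The ablation harness trains seven component combinations: the full model
and six cases that disable SuperPCA (→ per-scene global PCA to B bands),
CBAM (→ gates fixed at 1), the CNN trunk (→ per-position linear
projection of the raw reduced patch to z dimensions), or the
tokenizer+transformer (→ two-layer fully-connected head on flat G), in
the fixed combination table of the design.

## Problem sizes

All shipped experiments are sized for a single CPU: scenes are 64×64
(204 bands), patch sets subsample 40–200 labeled pixels per class
(adjacent pixels of one plot are near-duplicates, so quotas cost little
information), small-sample runs use a reduced but shape-valid
architecture (S=11, B=16), and test sets are capped at a few hundred
patches.  The acceptance script (`scripts/acceptance.py`) completes in
roughly 15 minutes; the test suite in under 15.

## Known limitations

* Simulator realism as listed above; in particular hard plot borders
  make patch mixing at boundaries harsher than in real imagery, and the
  absence of illumination structure makes masking easier.
* Because simulated plots are internally homogeneous with
  band-independent noise, SuperPCA shows no measurable advantage over
  per-scene global PCA in the small-sample ablation here (its per-segment
  bases introduce feature discontinuities where patches span segment
  boundaries, and there is no local covariance structure to exploit);
  the tokenizer+transformer and CNN components, by contrast, carry large
  and stable margins.  On heterogeneous multi-class mosaics — the regime
  superpixelwise reduction was designed for — the balance is expected to
  differ.
* ERS is O(E log E) in pure Python/heapq; fine to ~512² images, not
  tuned beyond that.
* The transformer is a single encoder block; depth, head count, token
  count and MLP width are configurable but unexplored beyond defaults.
* The SVM baseline's grid search is deliberately small (C ∈ {1, 10,
  100}, gamma ∈ {scale, 0.1}).
* Pixelwise 70/30 and 5/95 accuracies inherit spatial leakage; use the
  scene-level split for generalization claims.
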