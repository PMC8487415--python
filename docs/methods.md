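# Methods

## Problem setting

Somatostatin-receptor PET (⁶⁸Ga-DOTATATE) is the standard imaging modality
for gastroenteropancreatic neuroendocrine tumors, whose most common
metastatic site is the liver. Hepatic lesion detection is unusually hard on
these images: normal liver background uptake is high, and image noise is
substantially worse than in ¹⁸F-FDG PET (lower administered dose, faster
decay, inferior positron physics). `dotapet` implements an automated
detection pipeline for this setting — semi-automated gold-standard
annotation, a slice-wise residual U-Net, pixel-area noise filtering, and
object-level evaluation — exercised end to end on synthetic liver phantoms.

## Synthetic phantom model

Each study is a stack of trans-axial slices (default 64×64 pixels at
4 mm spacing, 23–71 slices; the reference experiment narrows this to 23–27
slices). The liver is a per-study ellipse (semi-axes ≈ 0.32/0.38 of the
grid, jittered center) filled with a uniform background activity; abnormal
studies additionally contain `round(N(4.0, 2.75²))` lesions clamped to
[1, 9], rendered as ellipsoids whose axial extent covers exactly 4–5
consecutive slices and whose in-plane radius is drawn from 6–14 mm. Lesion
uptake is `contrast × background` with contrast drawn from 2.0–3.5. The
structural image is blurred with a Gaussian point-spread function
(6 mm FWHM), then i.i.d. Gaussian noise is added and negatives are clipped
to zero.

Rendering order matters: blurring the *structure* first and adding noise
afterwards keeps the per-pixel noise SD exactly equal to the configured
`noise_sigma`, so the PERCIST background-SD semantics are exact. The
gold-standard label map records the **pre-blur** lesion extents — an
unambiguous target independent of the annotation stage.

Default intensity parameters (background 100, noise SD 10, contrast
2.0–3.5, blur 6 mm FWHM) are the package's own choice of a realistic
high-background/high-noise regime; no quantitative clinical values exist
for them. With these defaults every lesion's pre-blur uptake (≥ 200)
exceeds the modified PERCIST floor `1.5·100 + 2·10 = 170` — detectability
by construction, which can be disabled (`enforce_detectable=False`) to
study sub-threshold lesions.

What the phantom deliberately does **not** model: Poisson counting noise
and reconstruction correlations, attenuation/scatter, respiratory motion,
PET/CT misregistration, confluent or irregular lesions, diseased (cirrhotic
or steatotic) liver background. Consequently, passing phantom tests
demonstrates the *mechanics* of the pipeline (thresholding, boundary
recovery, learning, filtering, matching), not clinical performance.

## Semi-automated annotation

1. **Background spheres.** Three 3 cm spheres are placed in normal liver.
   Placement is automated and deterministic: candidate centers on a fixed
   grid are kept if the rasterized sphere fits inside the liver (and
   outside any exclusion map), and the three pairwise non-overlapping
   spheres whose local activity variance is *closest to the median*
   eligible variance are selected. Typical-variance selection — rather
   than minimum-variance — avoids the order-statistics bias of a minimum
   over hundreds of candidates (which underestimates the noise SD by
   ≈ 15%) while still rejecting lesions and liver edges, whose local
   variance is extreme. If the 3D sphere cannot fit the slice coverage, an
   equal-volume per-slice circle stack is used. The mean and SD are pooled
   over all pixels of the three spheres.
2. **Modified PERCIST threshold.** `1.5·μ_bg + 2·σ_bg`, exact arithmetic;
   comparison is strict (`activity > threshold`).
3. **Candidates.** Supra-threshold liver pixels grouped into 26-connected
   3D components (lesions are 3D objects at this stage); each component
   carries its peak pixel. On value plateaus the peak tie-breaks to the
   pixel nearest the component centroid, so boundary rays radiate from the
   lesion interior.
4. **Gradient-edge boundary.** From each slice's in-component peak, 32
   radial rays sample the image bilinearly at 0.25-px steps. Along each
   ray the boundary radius is the maximum-gradient location between the
   peak and one pixel past the first background-level crossing (ties —
   flat ramps under bilinear interpolation — resolve to the run midpoint).
   The enclosed region is realized as the **level set through the per-ray
   maximum-gradient points**: a pixel belongs to the lesion when its value
   reaches the edge level interpolated in angle between adjacent rays,
   within one pixel of the interpolated boundary radius; only the
   peak-connected region is kept. For a hard (step) edge the edge level
   sits mid-step, so the construction recovers the lesion's pixel set
   exactly; for a blurred edge it is the contour through the profile
   inflection — the classic gradient edge. (A literal polygon rasterized
   from the per-ray radii cannot be pixel-exact: the radius estimate has
   ~0.25 px error while in/out pixel distance gaps can be < 0.1 px.)
   Single-pixel candidates are returned unchanged with a warning record.
   The refinement search floor is `μ_bg + σ_bg`.

The physician accept/modify/delete step of a clinical workflow is
represented only by the provenance log; there is no interactive editor.

## Network

A 2D fully convolutional residual U-Net scores each slice independently
(outside-liver pixels are zeroed and the study is scaled to unit maximum
before inference — the in-memory analogue of the fixed 8-bit intensity
window used on disk):

* **Encoder** — four residual blocks (3×3 conv–BN–ReLU–3×3 conv–BN plus an
  identity or plain 1×1-conv projection shortcut, ReLU after the sum)
  joined by stride-2 3×3 convolutions; channel widths `c, 2c, 4c, 8c` with
  a `16c` bottleneck (default base `c = 32`; the reference experiment uses
  `c = 8`).
* **Decoder** — four residual blocks reached by stride-2 transposed
  convolutions (kernel = stride, i.e. non-overlapping learned upsampling);
  each long-range skip concatenates the encoder block's output with the
  upsampled features *before* the decoder block.
* **Contextual aggregation** — the two deepest decoder outputs (at 1/8 and
  1/4 resolution) are carried straight to full resolution by stride-8 and
  stride-4 transposed convolutions and fused by channel concatenation with
  the last residual block's output; a final 3×3 convolution and a sigmoid
  produce the 1-channel score map.
* **Padding contract** — inputs not divisible by 16 are reflect-padded to
  the next multiple and the score map is cropped back.

All layers (convolution via im2col/BLAS, transposed convolution, batch
normalization) and their backward passes are implemented in numpy inside
`dotapet.nn`; every backward pass is verified against central-difference
gradients in the test suite. Weights use He initialization from a seeded
generator; identical configs give identical weights, and all computation is
deterministic on CPU.

One numerical subtlety: the sigmoid output is clamped to
`[1e-7, 1 − 1e-7]`, the same δ used to clip probabilities inside the BCE
loss. This makes the gradient chained through the output layer exactly the
fused sigmoid+BCE gradient `(p − t)/N`; without the clamp, deeply saturated
score maps multiply the loss gradient by `p(1−p) ≈ 0` and training can
permanently collapse to the all-background solution (lesion pixels are
< 0.1% of the training pool).

## Training

Loss: `6·BCE + 1·Dice` (pixel-mean binary cross-entropy with probability
clipping δ = 1e-7; soft Dice `1 − (2Σpt+ε)/(Σp+Σt+ε)` with ε = 1e-6, zero
for the empty–empty case). Optimizer: momentum SGD (lr 0.01, momentum 0.9)
with polynomial decay `lr·(1 − it/max_it)^0.9`. Iterations are mini-batches
(default batch 8) of augmented liver-masked slices; augmentation applies a
shared random transform to image and label — horizontal flip (p = 0.5),
rotation ±10°, translation ±5% — with bilinear resampling for the image
and nearest-neighbor for the label so labels stay binary.

The full-scale budget is 100 000 iterations with 20 000-iteration patience;
the validation metric is pooled lesion-level F1 at the default detection
settings (binarize 0.05, area filter 15), computed every
`validation_interval` iterations. Training stops at the budget or when the
metric has not strictly improved for the patience window; the
best-validation checkpoint (weights and batch-norm buffers) is restored.
The replicate protocol retrains from `n_replicates` (default 5) seeds
derived deterministically from the master seed.

## Detection and evaluation

Score maps are binarized at a strict threshold (default 0.05), grouped into
8-connected components **within each slice** (the network treats slices as
discrete entities and filter sizes are quoted in pixels), and filtered by
pixel area: components with area below the filter are removed, area equal
to the filter is kept. The standard filter sweep is {5, 7, 10, 15, 20}.

Matching is greedy one-to-one by descending IoU between pixel sets on the
shared (slice, row, col) grid; a pair is accepted only when IoU > 0.05
(strict). Gold lesion maps are likewise decomposed into per-slice 2D
regions, so a prediction on the slice adjacent to a lesion's true extent
has IoU 0 and counts as a false positive — reproducing the characteristic
"edge of a true positive" error mode of slice-wise detection. The
annotation-recovery checks instead match 3D lesion objects (one component
per lesion id), since the annotation stage works in 3D.

PPV = TP/(TP+FP), sensitivity = TP/(TP+FN), F1 their harmonic mean, all
micro-averaged (pooled counts) over the test studies. Degenerate
convention: if there are no predictions and no gold lesions at all, every
ratio is 1.0 (a perfect empty answer); otherwise an undefined ratio is 0.0.
The PR curve sweeps the binarization threshold over a fixed score grid at a
fixed area filter; points are sorted by recall and the AUC is the
trapezoidal area over recall with the curve anchored at recall 0 by the
precision of its lowest-recall point (so a detector that is perfect at
every threshold scores exactly 1, and a silent one 0). Replicates are
aggregated as mean ± sample SD (n−1) per (metric, filter) cell; because
"F1 averaged over runs" and "F1 of the averaged PPV/sensitivity" can
differ, the aggregation grid reports both readings.

## Reference experiment (phantom scale)

`dotapet.protocol.run_reference_experiment` fixes the synthetic study
conditions used by the examples and by `scripts/acceptance.py`: 40 studies
(18 abnormal / 22 normal — roughly the clinical abnormal fraction), 64×64
grids, 23–27 slices, split 60/20/20 stratified by the abnormal flag, two
replicate networks with base width 8 trained for 800 iterations (patience
400, validation every 100). These sizes are the package's reference
configuration for synthetic experiments; every one of them is an ordinary
config field. On this protocol the held-out mean F1 at the best area
filter is ≈ 0.80–0.83, with PPV increasing and sensitivity decreasing as
the filter grows — the expected precision/sensitivity trade-off of
pixel-area noise filtering.

## Dataset format

Studies are directories named by a 5-digit numeric ID with three aligned
8-bit PNG image subdirectories (`pet`, `liver_mask`, `lesion_label`; masks
are 0/255) plus a `meta.json` sidecar recording the pixel spacing, slice
count, abnormal flag and the intensity window mapped onto 0..255. The
window makes the 8-bit scaling invertible up to half a quantization step;
without the sidecar, reading refuses to interpret intensities
quantitatively. Distinct lesion ids are recovered on read by 26-connected
labeling, which is valid because studies contain only non-confluent
lesions.

## Known limitations

* The phantom's Gaussian-noise/Gaussian-PSF model understates the
  difficulty of real reconstruction noise; phantom metrics are far above
  what any clinical cohort would yield.
* The network is 2D; no information flows between adjacent slices, and the
  evaluation inherits the slice-edge false-positive mode.
* The numpy engine is CPU-only and single-threaded beyond BLAS; full-scale
  (100k-iteration) training is possible but slow.
* The gradient-edge operator is a documented, reproducible stand-in for
  proprietary clinical tools; its agreement with any specific commercial
  implementation has not been assessed.
* DICOM/RT-structure ingestion is out of scope; the PNG + sidecar layout
  (optionally NIfTI-convertible via nibabel externally) is the only input
  path.
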