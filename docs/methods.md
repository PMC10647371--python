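# Methods

This note documents the models, conventions and numerical choices behind
`pelagiscan`, and what its synthetic benchmark does and does not show.

## Imaging model and calibration

The package assumes push-broom (line-scan) geometry: a cube of N scan lines
× M cross-track pixels × Lc bands, with a strictly increasing wavelength
axis of band centers in nm.  The nominal axis is 281 evenly spaced centers
over 400–1000 nm, matching a VIS-NIR bench-top instrument; any axis is
accepted.

Reflectance calibration divides raw counts by a white-standard frame,
entry-wise per band.  Because illumination and detector response vary
across the track but not along the scan, the reference is a single (M × Lc)
frame broadcast over scan lines.  Choices:

- **Zero guard.**  Reference entries below 1e-6 of the frame maximum are
  raised to that floor before division; an all-zero frame is an error.
- **Clipping.**  Reflectance is clamped to [0, 1] by default.  A ~99%
  diffuse standard means true reflectance can slightly exceed 1; a
  `clip=False` mode preserves such values for diagnostics.
- The reference frame is used exactly as captured — no rescaling by the
  standard's nominal 99% reflectance.

## Segmentation

Fish are isolated in two steps: Otsu's threshold on the band whose slice
maximises between-class variance (computed from a 256-bin histogram;
tie-break to the lowest band index; an override is available because band
choice is, in lab practice, sometimes manual), then 8-connected component
labeling.  Polarity is chosen so the foreground is the minority class,
which is correct whenever fish cover less than half the frame regardless of
whether they are brighter or darker than the board.  A single 3×3 closing
(configurable off) bridges one-pixel gaps from specular glint on scales.
Components under `min_area` (default 50 px) are dropped; masks are ordered
by leftmost column.  Coordinates are 0-based with half-open bounding boxes.

Touching or overlapping fish are out of scope: specimens are assumed laid
out separated, and no instance splitting is attempted.

## Spectral signatures

The whole-body signature averages reflectance per band **over mask pixels
only**.  The all-pixel (mask plus retained background) average is available
via `include_background=True`, but board pixels bias the curve toward the
board spectrum, so the mask-only average is the default.

RoI signatures draw R regions of P distinct pixels each, uniformly without
replacement within a region, regions allowed to overlap and not required to
be contiguous.  Each region uses a counter-derived substream of the seed
(`default_rng([seed, r])`), so draws are reproducible and independent of
evaluation order.  Defaults R = 1 signature per sample and P = 256 pixels
are engineering choices (the procedure itself does not fix them): P = 256
keeps the estimator's noise well below inter-species contrast while fitting
inside small fish masks.

Spectral reduction to Lc′ ≤ Lc uses linear interpolation onto Lc′ evenly
spaced wavelengths spanning the original range, preserving endpoints.
Lc′ = 200 by default so that the spectral CNN channel flattens to exactly
100 features (200 → 100 → 50 after two 2× pools, × 2 final filters).

## RGB emulation

Projection: camera channel i spans the half-open interval
[center−5 nm, center+5 nm); every hyperspectral band whose *center* falls
inside gets weight 1/n_i.  Columns are therefore convex combinations;
channels catching no band are zero and reported.  The default layout is 33
channels, 10 nm wide, centered 400–720 nm.

The bundled sensitivity table (`canon_like_33band.csv`) is **synthetic**:
Gaussian channel responses with B, G, R peaks at 460, 530, 600 nm and a
30 nm standard deviation, tabulated at the 33 camera centers.  It stands in
for a measured RGB-camera curve and uses the same CSV schema
(`wavelength_nm,R,G,B`), so any measured table drops in.

Rendering is linear — reshape to (N·M) × Lc, multiply by projection then
sensitivity, reshape — followed by 8-bit quantization.  Default gain is
per-image max normalization (deterministic, fixture-friendly); a fixed gain
mode exists for cross-image comparability.  Rounding is half-up.  No white
balance, gamma or colour management: the pipeline stays linear because the
classifier consumes the images directly.

## Augmentation and balancing

Standardization whites out non-mask pixels, then bilinearly resizes to a
square frame (256×256 by default) without preserving aspect ratio — a
1070×260 crop maps onto the full square.  Augmentation applies, in order:
horizontal/vertical flips (p = 0.5 each), rotation uniform in ±25°,
translation uniform in ±10% per axis, bilinear with white fill.  The ranges
are deliberately mild so the silhouette stays class-informative; all are in
`AugmentRanges`.

Balancing keeps originals verbatim and cycles them to synthesize the
deficit up to the per-class target; every synthetic sample pairs a fresh
geometric transform with a fresh RoI signature drawn from the same source
fish cube (the two input streams are augmented jointly but independently).
Augmentation seeds derive from one master generator, so a dataset is
reproducible byte-for-byte from its seed.

## The two-channel CNN

Each channel is two stages of conv → batch-norm → ReLU → 2× max-pool →
dropout (0.25); the head is dense(64) → ReLU → dropout → dense(C) →
softmax.  Filter counts (8, 16 spatial with 3×3 kernels; 4, 2 spectral
with length-5 kernels), Lc′ = 200 and the 64-unit head are pinned so the
two flattened feature vectors have exactly 65,536 and 100 entries at the
native geometry; the geometry is configurable and validated (the signature
length must be divisible by 4 to survive two pools).

Training: plain SGD at learning rate 0.05, batch size 32, categorical
cross-entropy, a stratified 33% validation split, early stopping when the
validation loss has not improved for `patience` (default 50) consecutive
epochs, best-validation weights restored.  Images are scaled to [0, 1];
signatures are fed as-is (already reflectance).  Inference disables
dropout and uses running batch-norm statistics, so prediction is
deterministic; probability ties resolve to the lowest class index.

The engine is a compact numpy implementation (`pelagiscan.nn`) with
explicit forward/backward passes; gradients are verified against central
finite differences in the test suite.  Same-seed runs are bit-reproducible
for a fixed BLAS configuration.

Baselines: one-vs-rest linear SVMs (C = 1) on z-scored spectral signatures,
[0,1]-scaled raw pixels, HOG descriptors (8 orientations, 16×16 cells, 4×4
blocks, L2-Hys; 21,632 features at 256×256), and concatenations.  Pixel and
HOG features are not standardized; the spectral block is z-scored with a
scaler fitted on the training fold.

## Evaluation

Per-class metrics use the one-vs-rest reduction (TP on the diagonal, FP
down the column, FN along the row, TN the remainder) and are aggregated
with true-class support as weights.  Under support weighting, weighted
recall is algebraically identical to global accuracy — the reason accuracy
and recall columns coincide in the comparison table.  Classes with zero
support and zero predictions report 0 with a warning rather than NaN.

Cross-validation is stratified at the sample level by default (matching the
5-fold 4000/1000 arithmetic on a 5000-sample dataset); a grouped mode
confines all augmented descendants of one physical fish to one fold.  The
grouped mode is the leakage-safe evaluation: with sample-level folds,
copies of one fish appear on both sides of the split and a model can score
above chance by memorizing fish identity rather than species.  The package
reports both modes in the full experiment.

Model comparison uses a two-sided Wilcoxon signed-rank test on paired
per-sample zero-one losses pooled over test folds.  Zero differences are
dropped; for n ≤ 25 nonzero pairs the p-value comes from the exact null of
the positive-rank sum, computed by dynamic programming over signed-rank
sums (equivalent to enumerating all 2^n sign assignments and valid under
tied ranks); for larger n a normal approximation with tie correction is
used.  Per-sample pairing is the only unit that can reach p < 0.05 with a
handful of folds.  No correction is applied across the seven pairwise
tests.

## Synthetic benchmark: what it emulates, and what it does not

`generate_scene` builds raw cubes the calibration inverts by construction:
board pixels carry a flat 0.15 reflectance; each fish is a tail-tapered
ellipse at a random non-overlapping pose whose pixels carry its species
curve; raw counts are reflectance × reference frame (a smooth halogen-like
illumination with mild cross-track vignetting, 3000 counts full scale).
Realism knobs: multiplicative lognormal pixel noise (σ = 0.02), a smooth
low-frequency texture gain in [0.8, 1.2], and per-fish size jitter
(s.d. 5%).

Species templates share a gentle baseline (0.40 rising to 0.45 across the
range) plus species-specific Gaussian peaks/valleys scaled by a single
difficulty knob Δ ∈ [0, 1]; pairwise template distance is exactly linear in
Δ, and Δ = 0 makes all species spectrally identical.  Two species have
distinctive silhouettes (a short slender one and a long broad one); the
other three share a silhouette **and** place their spectral features beyond
720 nm, outside the emulated camera's range, so neither shape nor rendered
colour separates them — only the VIS-NIR spectrum does.  One species
carries a pronounced 600 nm peak, mirroring the real-world observation that
merluza is most distinctive near 600 nm.

What passing synthetic tests shows: every pipeline stage is internally
consistent (calibration inverts the construction, segmentation recovers
ground-truth masks at Jaccard ≥ 0.95, signatures recover templates), and
the classifier behaves as the architecture intends — fused ≥ spectral-only
≫ spatial-only when species differ mainly spectrally, and spectral-only
falls to chance at Δ = 0.  What it does not show: performance on real fish.
Real scales, mucus, specularity, pose articulation and biological
within-species variation are absent, so synthetic accuracies (near 100% at
Δ = 1) say nothing quantitative about field performance.

## Problem sizes used by the test suite

The default test run exercises the full chain at desk scale, chosen as the
smallest sizes at which every qualitative effect is still visible: scenes
of 200×300 pixels × 60 bands, fish at 0.6 scale, 10 source fish and 100
balanced samples per class, 32×32 standardized images, Lc′ = 40, training
capped at 80 epochs with patience 12, and the grouped (leakage-safe)
train/test split with two scenes' fish held out.  At 32×32 the spatial
flatten (4,096) no longer swamps the 20-feature spectral flatten in the
fused head within a short epoch budget, which keeps the fused model's
advantage visible at small scale.  Dataset-arithmetic checks (class
balancing to 5 × 1000, 5-fold 4000/1000) run at full count with tiny
16×16 images, since only the bookkeeping is under test.  Architecture-size
checks always use the native 256×256×3 / Lc′ = 200 geometry.

## Known limitations

- No dark-current correction (raw frames are assumed dark-subtracted
  upstream or negligible).
- The CNN engine is CPU-bound numpy; it is meant for desk-scale
  experiments, not GPU-scale training.
- ENVI I/O covers the common integer/float little-endian BIL/BIP/BSQ
  rasters with a wavelength block, not the full header dialect.
- The Wilcoxon exact path assumes exchangeable signs under the null, as
  usual; with heavy ties among losses its p-values are conservative
  relative to a randomization test on the raw pairs.
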