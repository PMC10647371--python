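# pelagiscan

Spatial-spectral classification of pelagic fish species from VIS-NIR
hyperspectral cubes.

Fish-landing control requires telling apart species that look alike to the
eye — for Chilean pelagic fisheries these are *Engraulis ringens*
(anchoveta), *Merluccius gayi* (merluza), *Normanichthys crockeri* (mote),
*Stromateus stellatus* (pampanito) and *Strangomera bentincki* (sardina).
Hyperspectral imaging over 400–1000 nm records, for every pixel, a full
reflectance spectrum: an optical fingerprint that separates species of
similar size, shape and colour.  `pelagiscan` implements the complete chain
from raw line-scan cubes to a cross-validated species classifier, for
researchers and engineers prototyping optical catch-control systems.

## The method

1. **Reflectance calibration.**  Raw digital counts `A(i,j,λ)` are divided
   by a white-standard (Spectralon) frame `R(j,λ)` captured under the same
   illumination: `S(i,j,λ) = A(i,j,λ) / R(j,λ)`, clipped to [0, 1].
2. **Segmentation.**  A high-contrast band (maximum Otsu between-class
   variance) is thresholded; 8-connected components become per-fish binary
   masks, and each fish's bounding box is cropped through all bands.
3. **Spectral signatures.**  The whole-body signature is the per-band mean
   over mask pixels, `s̄(λ) = (1/|mask|) Σ S(i,j,λ)`.  For augmentation, R
   regions of interest of P randomly drawn mask pixels each are averaged,
   `Z_r(λ) = (1/P) Σ_p z_r^{(p)}(λ)`, and resampled to Lc′ ≤ Lc bands —
   an R × Lc′ signature array per fish.
4. **RGB emulation.**  A projection matrix (Lc × L_RGB) averages the narrow
   hyperspectral bands into 33 camera channels of 10 nm over 400–720 nm; an
   L_RGB × 3 camera sensitivity table then yields linear RGB, quantized to
   8 bits.
5. **Augmentation and balancing.**  Crops are standardized (white
   background, resized to 256×256), randomly flipped / rotated (±25°) /
   translated (±10%), and every class is balanced to a common target count,
   pairing each synthetic image with a fresh RoI signature.
6. **Two-channel CNN.**  A spatial channel (two stages of 3×3 conv →
   batch-norm → ReLU → 2× max-pool → dropout 0.25 over the RGB image,
   8 then 16 filters → 65,536 flattened features) and a spectral channel
   (the same pattern with length-5 1-D kernels over the Lc′ = 200 signature,
   4 then 2 filters → 100 features) are concatenated and classified by a
   dense softmax head.  Training: SGD (lr 0.05), batch 32, early stopping on
   a stratified 33% validation split.
7. **Evaluation.**  One-vs-rest accuracy / precision / recall / F1
   (support-weighted, so overall recall equals global accuracy), zero-one
   loss, stratified 5-fold cross-validation, learning curves, and paired
   Wilcoxon signed-rank comparison of per-sample losses between models.
   Linear-SVM baselines on spectral, raw-pixel, HOG and concatenated
   features provide reference points.

A synthetic scene generator produces raw cubes + reference frames of
fish-shaped objects with species-specific smooth reflectance curves, so the
whole pipeline runs and is tested without any measured data (see
`docs/methods.md`).

## Worked example

Generate a desk-scale synthetic experiment (5 species × 100 samples, 60
bands, 32×32 images), hold out all samples descending from two scenes'
fish, and train the fused CNN:

```python
import pelagiscan as p

ds = p.generate_experiment(n_per_class=100, seed=1, originals_per_class=10,
                           scene_shape=(200, 300), n_bands=60, fish_scale=0.6,
                           image_size=32, lc_prime=40, roi_pixels=128)

test = [i for i, s in enumerate(ds.samples) if s.provenance["scene"] >= 8]
train = sorted(set(range(len(ds))) - set(test))

arch = p.CNNConfig(classes=tuple(ds.classes), image_size=32,
                   input_signature_length=40)
model = p.build_cnn(arch, mode="fused", seed=0)
model, history = p.train_cnn(model, ds.subset(train),
                             p.TrainConfig(max_epochs=80, patience=12, seed=0))

labels = ds.labels()
pred, _ = p.predict(model, ds.subset(test))
report = p.metrics(p.confusion_matrix(labels[test], pred, ds.classes))
print(f"stopped after epoch {history.stopped_epoch} "
      f"(best validation loss at epoch {history.best_epoch})")
print(f"test accuracy  {report.accuracy:6.2f} %")
print(f"test precision {report.precision:6.2f} %")
print(f"test recall    {report.recall:6.2f} %")
print(f"test F1        {report.f1:6.2f} %")
```

Output (about a minute on one CPU core):

```
stopped after epoch 80 (best validation loss at epoch 80)
test accuracy  100.00 %
test precision 100.00 %
test recall    100.00 %
test F1        100.00 %
```

All 100 held-out samples are classified correctly: at full spectral
separation the five synthetic species are easy for the fused model, while a
spatial-only model on the same split reaches only ~60% because three of the
five species share a silhouette and their colours match.  The
`pelagiscan` CLI exposes the same stages for files on disk
(`calibrate`, `segment`, `signatures`, `render`, `synth`, `train`, `run`).

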