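# Methods

`endoseg` implements the analysis pipeline of a multimodal nonlinear
endomicroscope that records three co-registered contrasts per pixel —
CARS (lipid/protein-rich structures via the CH₂ stretch), TPEF (tissue
autofluorophores) and SHG (collagen fibers, cholesterol crystals) — and
turns large tiled acquisitions into tissue-class maps, diagnostic metrics,
image-quality figures and laser-ablation plans.  Because no raw patient
data are distributable, a synthetic-data module generates inputs with the
statistical structure the pipeline assumes; every stage is exercised and
tested end-to-end on those phantoms.

## Synthetic data

**Label maps.** Tissue regions are synthesised by thresholding smoothed
Gaussian random fields, one per class: each field is a seeded white-noise
raster convolved with a Gaussian of width `blob_scale_px` (default
`min(shape)/16`) and normalized to unit pointwise variance; a pixel takes
the class whose field plus offset is largest.  The per-class offsets are
adjusted iteratively (`offset += eta * (prior - realized)`) until every
realized fraction is within a quarter of the ±3-percentage-point
tolerance.  This is simple, deterministic given the seed, and produces
contiguous, histology-like regions.  The default six-class priors are the
cohort pixel fractions (background 56%, tumor 18%, other tissue 10%,
necrosis 7%, tumor stroma 7%, healthy epithelium 1%); as printed they sum
to 99%, so they are renormalized proportionally.

**Rendering.** Each class carries a `ChannelSignature`: a (CARS, TPEF,
SHG) mean triple in [0, 1], a texture correlation length (pixels) and an
additive Gaussian noise SD.  Defaults encode only the qualitative
contrasts of the tissue types — collagen-rich "other tissue" high in
SHG/TPEF and muscle-dominated CARS, tumor TPEF above tumor stroma,
SHG-bright stroma — with magnitudes that are package defaults, not claims
about real tissue.  Rendered intensities are clipped to [0, 1]; means
within ~2σ of the boundaries therefore acquire a small truncation bias,
which the tests avoid by construction.

**Tiling.** `decompose_into_tiles` cuts a mosaic into a raster-scan grid
with stage step `(1 − overlap) · tile_px` (10% overlap by default,
matching the acquisition protocol) and multiplies each tile by a radial
cosine vignette, `v(ρ) = 1 − s·(1 − cos πρ)/2`, which is 1 at the tile
center and `1 − s` at the corners — a qualitative model of edge falloff,
not an optical calculation.  Optional additive noise emulates detection
noise.

**Ablation phantom.** A brain-tissue stand-in: moderate CARS/TPEF and low
SHG background plus `n` elongated elliptical "cholesterol crystal" blobs
(default 40 px ≈ tens of micrometers at the 1.3 µm/px ablation-frame
sampling) whose SHG is several times the background mean.  Crystals are
placed with a minimum separation so the ground-truth mask has exactly `n`
connected components; placement failure raises after a bounded number of
retries.

What the phantoms do **not** model: optical PSFs, H&E appearance,
patient-to-patient variability, staining artifacts, or any quantitative
relation between tissue chemistry and channel intensity.  Passing tests
therefore demonstrate that the pipeline machinery is correct and
learnable signal is recovered — not that the model would reach any
particular performance on real tissue.

## Preprocessing

Stitching removes `crop_frac` (default 5%) of the tile size from each
border and places the cropped tiles edge to edge without blending, so
pixel values are conserved; the geometry is checked in integer pixels
(`tile_px − 2·crop_px` must equal the stage step), which requires
`overlap · tile_px` to be even — the 1200-px/10% protocol satisfies this.
Mosaics are percentile-normalized per channel over the full composite
(lower 1.5%, upper 99%), a monotone linear map with clipping; constant
channels map to zero with a warning.

Shading is corrected with a multiplicative flat-field estimated
retrospectively from the raw tile stack: per-pixel median across tiles,
Gaussian-smoothed with σ = tile_px/16, unit-mean normalized.  This is a
deliberate simplification of low-rank + smoothness flat-field estimators
(e.g. BaSiC): on vignetted flat phantoms it recovers the true profile with
r > 0.95 and halves the coefficient of variation, and segmentation has
been reported to be robust to the choice of correction.  A more elaborate
backend can be plugged in behind `ShadingModel`.

Registration of annotation masks uses phase correlation (sub-pixel, via
upsampled cross-correlation) for translation; the rigid path adds an
exhaustive rotation scan over ±5° in 0.25° steps, selecting the angle with
the lowest phase-correlation error.  Masks are resampled with
nearest-neighbour interpolation only, so the label set is exactly
preserved.  A landmark fallback (`register_from_landmarks`, 2-D Kabsch)
covers cases where intensity-based registration fails; failures below a
correlation threshold raise rather than silently resampling.

## Taxonomy

The 15-class inventory (background, epithelium, squamous epithelium,
necrosis, tumor, tumor stroma, dysplasia, stroma with inflammation,
muscle, connective, adipose, blood vessels, cartilage, glandular, other)
regroups to six meta classes (dysplasia → tumor; epithelium variants →
healthy epithelium; the seven benign stromal/structural types + other →
"other tissue") and further to three clinically motivated classes
(background; tissue to resect = tumor ∪ necrosis ∪ tumor stroma; tissue
to preserve = the rest).  The codebook ships as versioned YAML; the
15→3 map is required (and tested) to equal the composition 15→6→3.
"Inflammation" and "stroma with inflammation" are treated as the same
class.

## Segmentation

**Chessboard split.** The mosaic is partitioned into `patch_px` squares
(512 at full scale); patches with even (row + col) parity — the "white"
squares — are held out for testing and the rest train the model, so train
and test pixels never overlap.  Partial border patches are dropped from
both sets but covered at inference through reflect padding.

**Augmentation** applies, each with its own probability: perspective
jitter, rotation (±15°), flips, contrast and brightness changes, then a
random cut slightly larger than the model input followed by a center crop
(226 → 224 at full scale; scaled proportionally at desk scale).
Geometric transforms act identically on image and labels (labels with
nearest-neighbour interpolation); photometric ones on the image only.

**Architecture.** The classifier is a UNet3+ — every decoder stage fuses
3×3-convolved 64-channel skips from *all* encoder levels and deeper
decoder stages into a 320-channel fusion convolution — on a frozen VGG16
convolutional encoder (ImageNet widths; 14,714,688 parameters).  The
published description (224×224×3 input, five down-/up-sampling stacks,
six softmax outputs; four stacks and three outputs for the clinical
variant; totals 35.9 M/32.2 M with 14.7 M frozen in both) does not fully
determine the graph, and the printed totals are inconsistent with the
stock keras-unet-collection construction; the open element is fixed here
by the published parameter budget: a pooled bottleneck stage of three 3×3
convolutions at width 640 acts as the deepest down-sampling stack, and
the full backbone is instantiated (and counted, frozen) in both variants.
The resulting counts are 36,066,310 total / 21,351,622 trainable
(six-class) and 32,267,395 / 17,552,707 (three-class) with identical
frozen counts — within 0.5% of every published figure and exact for the
17.5 M trainable of the three-class variant.  Batch normalization is
omitted from the reconstruction; its parameters are a negligible ~10⁴ and
are frozen in the published setup.

**Training** uses Adam, sparse categorical cross-entropy, a held-out
validation split (50 tiles at full scale) and early stopping on the
validation loss (patience 20 of 400 epochs at full scale) with
best-weights restoration.  Because no GPU framework is assumed, training
runs on an in-package numpy autodiff engine (same-pad im2col convolution,
ReLU, 2×2 max-pool, nearest upsampling, concat, softmax-CE, Adam) whose
gradients are verified against finite differences.  The engine trains the
**reduced-width desk-scale variant**: the same topology with widths scaled
by `width_factor`, one convolution per encoder stack, and a trainable
encoder (a seeded random frozen encoder is available via
`freeze_encoder`).  The desk variant is flagged (`ModelSpec.desk_scale`)
and never used for parameter-count checks.

**Tiled inference.** Each mosaic is segmented `n_shifts` = 20 times with
the tile grid offset differently each time; offsets are drawn without
replacement from a seeded uniform grid over [0, input_px)², with (0, 0)
always first so a single shift reduces to plain tiling.  The mosaic is
reflect-padded to full tile cover per shift.  The final per-pixel label is
the majority vote across shifts; ties break by the largest accumulated
softmax score, then the lowest class index — deterministic, score-aware,
and order-invariant by construction.

**Desk-scale study conditions.** The learning check trains the reduced
model (width 1/16 → taps 4/8, bottleneck 40, skip 4, fusion 20; 2 stacks;
48-px input) on 320×320 six-class mosaics split into 64-px chessboard
patches, 40 epochs × 5 steps of batch 8 at learning rate 5·10⁻³, and
evaluates macro-F1 on the white-parity pixels via 5-shift voting.  Across
three seeds this reaches macro-F1 ≈ 0.97 (threshold 0.85).  Classes absent
from the held-out parity (possible for the 1%-prior epithelium on small
rasters) are reported as undefined and excluded from the macro average,
per the metric contract.

## Evaluation

Per class, one-vs-rest: specificity S = TN/(TN+FP), sensitivity
R = TP/(TP+FN), precision P = TP/(TP+FP), F1 = 2PR/(P+R); macro values
are unweighted means over classes, so prevalence does not enter.
Undefined ratios (zero denominators) yield NaN, a warning, and exclusion
from the macro.  Report tables round half-up to two decimals, matching
the published tables; macro averages are computed from unrounded
per-class values.  Recomputing F1 from *rounded* table entries can differ
from a published cell by one unit in the last digit when the true value
sits near a rounding boundary (e.g. F1(0.80, 0.81) = 0.80497); the
acceptance test therefore allows exactly that one-ULP propagation on F1
cells while holding macro averages to printed precision.

## Quality metrics

**Single-image FRC.** The channel is center-cropped to an even square and
split into the even/even and odd/odd 2×2-decimated sub-lattices.  The
odd/odd lattice is offset by half a sub-pixel diagonally, which imposes a
spectral phase ramp `exp(2πi(fx+fy)/2)` on a common scene; this ramp is
removed before correlation, otherwise high rings of a perfectly shared
scene would anti-correlate.  Ring-wise normalized cross-correlation of
the two spectra is smoothed by a centered 13-bin moving average ("13-pixel
size" read as radial bins), the DC ring being replaced by its neighbour
(after mean subtraction it carries only numerical noise).  The resolution
is `2 · pixel_size / f_cross`, where `f_cross` is the first crossing of
the 1/7 threshold by linear interpolation and the factor 2 compensates
the halved sampling of the sub-images; a curve that never crosses reports
an infinite "beyond Nyquist" sentinel.  On low-pass phantoms with known
cutoff the estimate lands within 15% (slightly conservative: the
smoothing window drags the crossing outward by a few bins).

**C_RMS** is the population SD of the pixel intensities.  **SNR_σ** is
`20·log₁₀((s_max − μ_bg)/σ_bg)` in dB with μ_bg/σ_bg from a selected
background region; by default the lowest-mean 5%×5% corner block, since
only "a selected background region" is specified.  A zero-SD background
raises; `s_max ≤ μ_bg` warns and reports the log-domain value as-is.

## Ablation planning

A normalized frame is clustered by K-means (k = 4, k-means++, seeded) on
raw per-pixel channel triples — no spatial features, the simplest reading
of dividing the image into independent intensity regions.  The cluster
with the highest **mean** SHG (mean rather than total; recorded in the
criterion field) becomes the raw mask, ties resolving to the lowest index
with a warning.  The mask is median-filtered and morphologically closed
(radius 3 px each by default; the filtering scale is otherwise
unspecified) and exported as a scanline-ordered binary raster with JSON
geometry for the acousto-optic modulator.  `simulate_ablation` attenuates
masked pixels by a per-frame removal fraction (default 0.26, chosen so
that 8 consecutive frames leave < 10% of the initial intensity) and never
touches pixels outside the mask.  On crystal phantoms the full
cluster→select→filter chain reaches recall ≥ 0.9 on crystal pixels with
false-positive rate ≤ 0.05 over ten seeds.

Physics helpers: CARS wavenumber `10⁷/λ_pump − 10⁷/λ_Stokes` (nm →
cm⁻¹); pulse energy = average power / repetition rate (mW, kHz → µJ).

## Numerical choices and limitations

- All intensities live in [0, 1] floats; 16-bit quantization only at TIFF
  export.  Coordinates are origin top-left, row-major, 0-based, half-open.
- Stitching requires exact integer crop/step agreement and raises
  otherwise, stating the expected crop.
- K-means determinism relies on seeded k-means++ with 4 restarts;
  well-separated phantoms yield seed-independent partitions.
- The desk-scale engine is float64 and single-threaded; it is adequate
  for ≤10⁶-parameter models and small mosaics, and is not a substitute
  benchmark for full-scale training.
- The FRC estimate assumes approximately isotropic content and
  uncorrelated noise between sub-lattices; structured (e.g. line-scan)
  noise would correlate the half-images and bias resolution optimistic.
- Registration handles translation + small rotations only (the scan is
  ±5°); large rotations or nonrigid deformation are out of scope, as is
  exact reproduction of BaSiC.
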