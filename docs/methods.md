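# Methods

## Overview

`stromascope` quantifies the tumor-stroma reaction (TSR) — the desmoplastic
change in stroma adjacent to invasive tumor — from whole-slide H&E images,
and relates the resulting slide-level scores to survival and gene
expression.  The per-slide chain is

1. **Foreground detection and tiling.**  The slide is converted to CIELAB;
   a pixel is tissue iff its lightness L falls below a threshold.  256x256
   patches are enumerated on a stride lattice (stride 128 for training
   sets, non-overlapping stride 256 for inference); a patch whose
   full-resolution background fraction exceeds 50% is excluded.
2. **Patch models.**  Two pluggable backends: a segmenter mapping a patch
   to a per-pixel {background, tumor, stroma} raster, and per-criterion TSR
   scorers mapping a patch to a grade in {0, 1, 2} (criteria: fibrosis,
   stromal cellularity, stromal-cell orientation) with class
   probabilities.  Trained networks can be dropped in; the shipped
   reference backends are classical (below).
3. **Stitching.**  Each patch's dominant class (majority over its tissue
   pixels, ties toward stroma) is painted over its down-scaled footprint,
   producing a slide mask at scale r (default 1/128, the scale the
   interface formula is defined at).
4. **Interface detection.**  With I_T, I_S the tumor/stroma indicators of
   the slide mask and S a structuring element,

       Tumor_core  = closing(I_T, S)
       Stroma_core = closing(I_S, S)
       interface   = (dilate(Stroma_core, S) XOR erode(Stroma_core, S))
                     AND Stroma_core AND dilate(Tumor_core, S)

   i.e. the inner morphological-gradient band of the stroma core,
   restricted to stroma actually touching tumor.  The XOR form is kept
   literally (it is verified pixel-identical against an independent
   brute-force composition of the operators).  All operators treat pixels
   outside the image as empty.  The top-5 largest 8-connected components
   are the representative interface regions.
5. **Summarization.**  Over stroma patches intersecting the interface
   (any overlap by default; the membership fraction is configurable),
   per criterion: the normalized score distribution (ratio_0/1/2), the
   mean score (= ratio_1 + 2 ratio_2) and the population SD.  All patches
   carry equal weight.
6. **Association.**  Median split of a chosen feature (fibrosis mean score
   by default; ties at the median go to the low group), Cox proportional
   hazards (univariate, and multivariable adjusted for age, stage IV vs
   III, and suboptimal debulking) via partial likelihood (lifelines), with
   HR, 95% CI and two-sided Wald p.  Molecular side: per-gene Spearman
   rank correlation (average ranks for ties; t-approximation p-values,
   cross-checked against scipy per gene), nominal p < 0.05 selection split
   by correlation sign, and one-sided hypergeometric over-representation
   against user gene sets (GMT) with Benjamini-Hochberg FDR across the
   collection.  The enrichment universe is the measured gene list.

## Reference backends

The deep architectures used in cohort-scale TSR studies require trained
weights that are not distributable here, so the package defines backend
*contracts* and ships classical reference implementations good enough to
exercise the full pipeline on phantoms:

* **Segmenter** — a depth-10 decision tree over per-pixel features
  (R, G, B, and local gray-level SD in a 5x5 window), trained on up to
  200k subsampled pixels.  On phantoms with the default texture
  separation it exceeds 99% pixel accuracy.
* **TSR scorer** — a patch's ground-truth grade is the *modal* grade over
  its stroma pixels, so the scorer mirrors that definition: a per-pixel
  classifier assigns each (stride-2 subsampled) pixel to grade 0/1/2 or
  "other" (tumor/background); the patch's class probabilities are the
  normalized grade-probability mass and the prediction its argmax.  A
  whole-patch summary-feature classifier was tried first and failed on
  patches straddling grade bands (ambiguous mean features, unambiguous
  modal label); the pixel-modal design removes that failure mode.

Determinism: both backends are deterministic given their fit seed.

## Synthetic phantoms — what they emulate and what they do not

Phantom slides place smooth tumor blobs inside an elliptical tissue region
on a bright background.  TSR grade decays with Euclidean distance from the
nearest tumor pixel (grade 2 within 80 px, grade 1 within 200 px at the
default 1024 px slide; 160/400 px at the 3072 px cohort scale), creating a
true desmoplastic band at the tumor border — the object the interface
formula is supposed to find.  Carcinoma-like slides carry the graded
reaction; borderline-tumor-like slides have identical anatomy but grade 0
everywhere, mirroring the negative-control role of borderline cases.
The four (class, grade) textures use disjoint base-color ranges with
grade-dependent stripe/dot modulation, so classical color classifiers can
succeed by construction; a "hard mode" with narrower separation exists for
robustness experiments.

The phantoms deliberately do **not** model: realistic H&E color
statistics or stain variation, nuclei and cellular texture, necrosis,
adipose tissue, pen marks, or scanner artifacts.  Passing the phantom
suite therefore demonstrates that the pipeline machinery (tiling,
aggregation, morphology, statistics) is correct — not that the reference
backends would segment real tissue.  On real slides the backends should be
replaced by trained models through the two contracts.

Synthetic cohorts plant known effects: exponential survival with the
hazard multiplied by exp(log HR) for the fibrosis-high half
(administrative censoring at 150 months; baseline hazard 1/40 per month,
giving a median near 28 months and an event fraction near 90%, in line
with advanced serous carcinoma cohorts), and a chosen fraction of genes
depending linearly (slope 0.7, unit noise) on the standardized fibrosis
score.  Age (N(63, 11), clipped 24-89), stage (25% IV) and debulking
(24% suboptimal) are drawn independently at frequencies typical of such
cohorts.

## Numerical and design choices

* **Foreground threshold.**  `detect_foreground` defaults to Otsu's
  automatic threshold on the L channel with a fixed-value override
  (default L < 85); a constant image falls back to the fixed default.
  The end-to-end pipeline helper uses the fixed rule: on slides whose
  tissue is strongly multimodal (dark tumor + pale stroma) the automatic
  bimodal split can land between tissue classes rather than between
  tissue and glass (measured on phantoms: Otsu 70 vs glass L 96, pale
  stroma L 82, misreading pale stroma as background).
* **Coordinates.**  0-based, x right / y down, half-open pixel intervals;
  edge tiles are dropped, not padded.  Background fraction is recomputed
  at full patch resolution, not read off the downsampled mask.
* **Mask scale vs structuring element.**  At r = 1/128 a 256 px patch
  stitches to a 2x2 block, so the slide mask is piecewise constant on
  2 px blocks.  Closing with any element comparable to or larger than the
  block reshapes the staircase boundary and silently absorbs thin tumor
  corners into the stroma core; measured band recovery on phantom truth
  masks was 56-63% with a disk of radius 2.  The phantom end-to-end study
  therefore runs at r = 1/64 (4 px blocks) with a 3x3 square element —
  recovery is then 100% on truth masks — while the library defaults stay
  at r = 1/128 with a disk of radius 2 for API compatibility with the
  formula's native scale.  Rule of thumb: keep the element no larger than
  the stitched block.
* **Interface truth at patch granularity.**  The stitched mask cannot
  resolve anything finer than one patch, so phantom interface recovery is
  judged against the ground-truth *dominant class per tile* stitched the
  same way (with the same background-exclusion rule), and the true band is
  "truth stroma within one element radius of truth tumor" at that scale.
  A related limitation: the formula cannot recover band pixels where the
  stroma strip between tumor and glass is thinner than the element, so
  cohort phantoms place tumor blobs centrally.
* **Both-empty convention.**  Dice and IoU are defined as 1 when both
  masks are empty, keeping batch evaluation of background-only tiles
  NaN-free.  AP is pixel-level rank-based area under the
  precision-recall curve (ties grouped); it errors when the truth has no
  positives.
* **Extrinsic review quantiles.**  Type-1 (inverted CDF) empirical
  quantiles, computed from explicit order statistics (immune to q*n
  floating-point slop), with the upper tail mirrored so the two 5% tails
  select symmetric counts.  All-equal ratios degenerate to selecting
  every slide, with a warning.
* **Review sample size.**  At least 10 and strictly fewer than 30 patches
  per slide, capped at availability (warning below the minimum); uniform
  without replacement, deterministic per seed.
* **Overlap semantics in annotations.**  Scored sub-regions are assumed
  homogeneous and disjoint; on overlap the later feature wins (file
  order) with a warning.  Pixel membership tests polygon containment at
  pixel centers (even-odd rule; self-intersecting polygons are rejected
  at parse time).
* **Median-split ties** go to the low group; an all-identical feature is
  an error rather than a single-group "split".
* **ORA universe** is the measured gene list (all genes on the expression
  matrix); gene sets are intersected with it before testing.

## Problem sizes used by the test suite and acceptance script

Training phantoms are 1024 px square (3 carcinoma-like + 2
borderline-like, stride-128 tiling, 245 labeled patches); held-out
accuracy uses 2 further slides (98 patches).  The end-to-end study runs
10 carcinoma-like and 3 borderline-like phantoms at 3072 px.  Survival
properties use 50 replicates of n = 400 cases; molecular properties use
cohorts of 200 cases x 1000 genes (10% planted), with 20 replicates for
the enrichment ranking and 50 candidate gene sets per replicate.
Morphology equivalence uses 100 random 64x64 masks across three
structuring elements.

## Known limitations

* The reference backends are phantom-grade, not histology-grade; real
  deployments must plug trained models into the contracts.
* Interface detection inherits segmentation errors by construction; a
  wrong dominant class on one patch moves the local interface by a full
  patch.
* The per-gene Spearman p-value uses the t-approximation, which is the
  standard large-sample test but approximate below ~10 cases.
* No stain/color normalization is provided; slides from different
  scanners or staining batches need external harmonization before the
  backends (reference or learned) can be trusted.
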