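# stromascope

Whole-slide quantification of the **tumor-stroma reaction (TSR)** — the
desmoplastic change (fibrosis, stromal cellularity, stromal-cell
orientation, each graded 0/1/2) that stroma undergoes next to invasive
tumor — and association of the resulting slide-level scores with patient
survival and tumor gene expression.

It is aimed at computational-pathology researchers who want the
*machinery* of a TSR pipeline — tiling, backend-agnostic patch models,
interface morphology, summarization, statistics — as tested, reusable
parts: plug in your own trained segmentation/scoring models and run the
same chain on real whole-slide images, or use the built-in synthetic
phantoms to validate every stage end to end without any data download.

## The core computation

Patch-level tumor/stroma segmentation is stitched (down-sample r, default
1/128) into a slide mask with indicators I_T (tumor) and I_S (stroma).
The tumor-stroma **interface** — the stromal band hugging the invasive
front, where TSR is assessed — is a fixed morphological composition with
structuring element S:

```
Tumor_core  = C(I_T, S)                        # closing
Stroma_core = C(I_S, S)
interface   = (D(Stroma_core, S) ⊕ E(Stroma_core, S))   # dilation XOR erosion
              ∧ Stroma_core ∧ D(Tumor_core, S)
```

The top-5 largest connected components of `interface` are the
representative regions.  TSR scores of stroma patches inside the
interface are summarized per slide into the normalized score distribution
(ratio_0/1/2), mean and SD per criterion; slides are then median-split on
a feature (fibrosis mean score by default) and compared by Cox
proportional-hazards regression (univariate and adjusted for age, stage
IV vs III, debulking), and genes are ranked by Spearman correlation with
the feature, with one-sided hypergeometric over-representation (BH FDR)
against user gene sets.

See `docs/methods.md` for assumptions, parameter defaults and the design
rationale behind every numerical choice.

## Worked example

Train the classical reference backends on labeled phantom patches, then
run the full chain on a fresh phantom slide:

```python
from stromascope.synthetic_data import (PhantomConfig, CRITERIA, SBOT_LIKE,
                                        generate_phantom_slide,
                                        generate_labeled_patches)
from stromascope.tiling_io import TilingConfig
from stromascope.patch_models import (fit_reference_segmenter,
                                      fit_reference_tsr_scorer)
from stromascope.pipeline import run_slide

tile = TilingConfig(stride=128)
train = []
for seed in (0, 1, 2):                      # carcinoma-like, graded TSR
    s = generate_phantom_slide(PhantomConfig(seed=seed), slide_id=f"train{seed}")
    train += generate_labeled_patches(s, tile)
for seed in (100, 101):                     # borderline-like negatives
    s = generate_phantom_slide(PhantomConfig(seed=seed, label=SBOT_LIKE),
                               slide_id=f"neg{seed}")
    train += generate_labeled_patches(s, tile)

segmenter = fit_reference_segmenter(train, seed=0)
scorers = {c: fit_reference_tsr_scorer(train, c, seed=0) for c in CRITERIA}

slide = generate_phantom_slide(PhantomConfig(seed=42), slide_id="demo")
result = run_slide(slide.image, segmenter, scorers, slide_id="demo")

f = result.features.features["fibrosis"]
print(f"interface components: {len(result.interface.components)}")
print(f"interface patches:    {result.features.n_interface_patches}")
print(f"fibrosis ratios:      {f['ratio_0']:.2f} / {f['ratio_1']:.2f} / {f['ratio_2']:.2f}")
print(f"fibrosis mean (SD):   {f['mean_score']:.2f} ({f['sd_score']:.2f})")
```

Output:

```
interface components: 1
interface patches:    3
fibrosis ratios:      0.00 / 0.67 / 0.33
fibrosis mean (SD):   1.33 (0.47)
```

One interface region was found; of the three stroma patches touching it,
two were scored fibrosis grade 1 and one grade 2, giving a mean fibrosis
score of 1.33 — a strong stromal reaction, as planted next to the tumor
border of a carcinoma-like phantom (a borderline-like slide scores 0.00).

The same stages are scriptable from a shell, e.g. a survival association
on a synthetic cohort with a planted fibrosis hazard (log HR 0.69):

```
$ stromascope synth cohort --out cohort --seed 3 --n-cases 60 --n-genes 200
$ stromascope assoc cox cohort/clinical.csv --feature fibrosis_score --out cox.csv
 covariate   log_hr      hr  ci_lower  ci_upper        p
group_high 0.672547 1.95922   1.12984  3.397424 0.016638
```

The fibrosis-high half shows a hazard ratio near the planted value of 2
(95% CI 1.13-3.40, p = 0.017).  Other subcommands: `stromascope synth
slide`, `tile`, `annot`, `interface`, `assoc genes`, `assoc ora`.

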