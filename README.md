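# mscolo — pixel-wise neoplasia classification for multispectral colonoscopy

Flat or small neoplastic lesions in the colon are easy to miss under white
light. Multispectral endoscopy acquires one narrow-band image per
illumination wavelength — here seven bands from near-UV to red (396, 438,
475, 512, 542, 575, 628 nm) — giving every pixel a coarse reflectance
spectrum that differs between healthy mucosa and neoplastic tissue.
`mscolo` implements a complete, tested pipeline that classifies every pixel
of such a 7-band cube as lesion or healthy tissue, for researchers working
on spectral endoscopy and tissue classification.

Because no in-vivo multispectral colonoscopy dataset is publicly available,
the package ships a first-class synthetic cohort generator with known
ground truth (band-dependent reflectance, lesion texture, specular
highlights, vignetting, sensor noise), so every stage is testable and the
pipeline's statistical behaviour can be validated end to end.

## The pipeline

1. **Pre-processing** — exclude pixels whose red- or yellow-band intensity
   falls below 5% of that band's maximum (plus a 5 px surrounding), smooth
   with a 7×7 σ=1 Gaussian, exclude a 5 px margin around the drawn lesion
   boundary, normalize each band by its image maximum
   `I_norm(x,y,λ) = I(x,y,λ) / max_{x,y} I(x,y,λ)`, denoise with a
   tile-wise (20×20 px) minimum noise fraction (MNF) transform whose noise
   model is a support-vector regression of each band on the remaining
   bands, drop the three lowest-SNR components, de-normalize, and smooth
   with an 11×11 σ=2 Gaussian.
2. **Features** — per pixel: the 7 band intensities; Sobel derivatives;
   spectral–spatial variation (windowed per-band SD and across-band SD of
   the local mean spectrum); and a rotation-invariant Gauss–Laguerre bank

   `LG_l^p(ρ,Θ;r) = exp(−(ρs)^{2/q}) (ρs)^{l/q} [cos(l(Θ + 2rπ/max(2l,1))) · L_p^l(ρs·arctan(ρs))]^{3−q}`

   with q=2, s=18 on a 40×40 grid, l∈0..4, p∈0..3, pooled as the maximal
   absolute response over r∈{0, 0.25, 0.5, 0.75, 1} (169 columns in total).
3. **Reduction** — PCA keeping 99% of the training variance (typically a
   few tens of components).
4. **Classification** — random forest (400 trees, leaf size 3), RobustBoost
   (100 stumps, error goal 0.2), AdaBoost (400 stumps, learning rate 0.1),
   and linear / Gaussian SVMs (standardized, automatic kernel scale,
   outlier fraction 0.05), trained on a random 1% of the training rows.
5. **Evaluation** — leave-one-animal-out: each fold trains on all other
   animals and predicts every valid pixel of the held-out animal. Metrics
   per fold, averaged over folds: ACC, balanced accuracy
   ACC2 = (Sen+Spe)/2, rank AUC, and the Matthews correlation coefficient
   `MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))`.
   A threefold ANOVA (classifier × metric × spatial features) with partial
   η² quantifies what drives the differences.

## Worked example

```python
from mscolo import texture_contrast_params, generate_cohort
from mscolo.pipeline import preprocess_cohort
from mscolo.preprocessing import PreprocessConfig
from mscolo.features import FeatureConfig, build_feature_table
from mscolo.model import loo_crossvalidate, default_classifier_specs
from mscolo.evaluation import aggregate_folds

params = texture_contrast_params(n_animals=8, seed=13)   # 64x64 px frames
cohort = generate_cohort(params)
processed = preprocess_cohort(cohort, PreprocessConfig())
for spatial in (True, False):
    table = build_feature_table(processed, FeatureConfig(spatial=spatial))
    results = loo_crossvalidate(table, default_classifier_specs(),
                                seed=1, subsample_fraction=0.05)
    arm = "spatial" if spatial else "intensity-only"
    print(arm, {k: round(aggregate_folds(f).mcc, 3)
                for k, f in results.items()})
```

prints

```
spatial {'RF': 0.527, 'RB': 0.582, 'AB': 0.575, 'SVM_lin': 0.704, 'SVM_gauss': 0.636}
intensity-only {'RF': 0.391, 'RB': 0.354, 'AB': 0.374, 'SVM_lin': 0.174, 'SVM_gauss': 0.214}
```

This cohort's lesions have the *same mean reflectance* as healthy tissue in
every band and differ only in texture; the intensity-only arm has little to
work with, while the spatial-feature arm lifts the mean leave-one-out MCC
for all five classifiers — the texture information is carried by the
Sobel/SSV/Gauss–Laguerre columns.

## Command line

```bash
mscolo run --out results/run --seed 1                 # full pipeline
mscolo simulate --config cohort.yaml --out DIR        # or stage by stage:
mscolo preprocess --in DIR --out PREP
mscolo features --in PREP --out feat.npz --spatial on
mscolo train-eval --features feat.npz --seed 1 --out EVAL
mscolo report --runs EVAL --out REPORT
```

The staged commands compose to exactly the same outputs as `mscolo run`.
The numbered scripts under `analysis/` run the same study design
(simulate → preprocess → features → cross-validate → report/ANOVA) as a
narrative sequence, writing tables under `results/`.

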