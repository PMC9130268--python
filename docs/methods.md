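# Methods

This note documents the models, parameter choices and numerical decisions
behind `mscolo`, and what the synthetic validation does and does not show.

## Problem setting

The pipeline performs pixel-wise binary classification (neoplastic lesion
vs. healthy mucosa) on 7-band multispectral endoscopy cubes
I(x, y, λ) with centre wavelengths 396–628 nm. Evaluation is
leave-one-animal-out: a model never sees any pixel of the animal it is
tested on, which is the only split that honours the strong spatial and
biological correlation of pixels within one animal.

## Synthetic cohort generator

No public in-vivo dataset of this kind exists, so the generator is a
first-class component rather than a test fixture. One animal is simulated
as:

* **Reflectance.** Healthy tissue uses a fixed 7-vector of per-band diffuse
  reflectance values rising from near-UV (0.15) to red (0.72); lesions use
  a second vector. Only the qualitative ordering is constrained by
  observation (UV/blue darkest; healthy relatively brighter than lesion in
  yellow/red compared to green); the absolute levels are this package's
  choice and are configurable per band, which is how class contrast is
  controlled.
* **Lesions.** Unions of 1–3 discs with smooth low-order boundary
  perturbations (cosine modes 2–4, ~6% radial SD), placed fully inside the
  frame. Radii default to 30–80 px at the 520×496 acquisition size and are
  rescaled for small test frames.
* **Texture.** Band-correlated low-pass Gaussian random fields (unit
  variance, correlation length `texture_scale_px`), scaled per band by the
  healthy reflectance profile. Lesion texture may have its own amplitude
  and scale. When lesion and healthy texture statistics are identical a
  *single continuous field* covers the frame: stitching two independent
  realizations at the boundary would leave a faint seam that classifiers
  can detect, silently breaking any "zero contrast" condition.
* **Artefacts.** Specular highlights are near-saturated discs painted over
  the scene; vignetting multiplies by 1 − v·(r/r_max)^γ; optional per-band
  gain jitter; i.i.d. Gaussian sensor noise; saturation is modelled by
  clipping to [0, 1]. The full-frame defaults (v = 0.999, γ = 1.8) were
  calibrated once so that the dark-pixel exclusion removes ≈1% of a
  520×496 frame; the desk-scale presets use corner-only vignetting
  (v = 0.6, γ = 3) so the small field of view keeps its mid-field
  intensity.
* **Groups.** Animals are tagged spontaneous/inflammation in a 14:11
  proportion to exercise the subgroup reporting.

Motion between band acquisitions is *not* simulated (motion-affected
series are discarded before analysis in practice), and no attempt is made
at photorealism or physical haemoglobin-based reflectance modelling.
Consequences for interpreting results: passing tests show the pipeline
recovers signal that is in the data and reports chance when none is, not
that these accuracy levels transfer to real mucosa.

## Pre-processing

Stages run in a fixed order (each exclusion only ever shrinks the valid
set):

1. **Specular/dark exclusion.** A pixel is invalid iff its red- or
   yellow-band intensity is below 5% of that band's per-image maximum;
   all pixels within 5 px (Euclidean disc; Chebyshev available) are also
   excluded. The threshold reference is the per-band, per-image maximum —
   consistent with the normalization — not the sensor full scale.
2. **Gaussian 7×7, σ=1** (truncated, normalized kernel; reflect borders),
   so the MNF does not propagate single-band noise artefacts across bands.
3. **Lesion-margin exclusion.** 5 px on both sides of the drawn boundary
   are removed from training and testing; the margin location itself is
   uncertain.
4. **Normalization** I_norm = I / max_{x,y} I per band (maxima saved and
   restored after the MNF). The maximum is computed over all pixels,
   including ones later excluded.
5. **MNF denoising** on 20×20 tiles: per tile, noise is estimated by
   regressing each band on the remaining bands (RBF support-vector
   regression, C=1, ε=0.01, γ='scale'; multilinear regression and a
   horizontal shift-difference are selectable), the data are whitened by
   the noise covariance, the whitened covariance is eigendecomposed
   (components ordered by SNR), the trailing 3 components are zeroed, and
   the transform is inverted. A singular noise covariance is ridge-
   regularized (logged); constant tiles fall back to shift-difference
   noise; tiles with fewer pixels than bands+2 pass through unchanged;
   a trailing sliver thinner than that is merged into its neighbour.
   With `n_drop=0` the transform is an identity to ~1e−12, which is the
   main numerical self-check.
6. **De-normalization**, then **Gaussian 11×11, σ=2**.

Coordinates are 0-based (row, column); convolution borders use reflect
padding throughout (the choice is otherwise unconstrained).

## Features

Four families per pixel (169 columns with the default ranges):

* intensity (7), Sobel horizontal/vertical per band (14),
* spectral–spatial variation (8): per-band SD in a 7×7 window plus the
  across-band SD of the 7×7-mean spectrum. The original definition of
  this family lives in prior work that is not restated here; this windowed
  interpretation is a documented placeholder of this package.
* Gauss–Laguerre bank (140): per band and (l, p), l∈0..4, p∈0..3, the
  maximal absolute correlation response over r∈{0,…,1} in steps of 0.25.

Kernel details: 40×40 grid with half-pixel centring (making the grid exact
under 90° rotations), ρ normalized by the kernel half-width, Θ measured
from the +x axis. The radial envelope uses exp(−(ρs)^{2/q}): the positive
exponent in the printed form of the formula grows without bound in ρ and
cannot produce localized kernels; the decaying sign reproduces the
intended bounded, ring-shaped filters and the positive sign remains a
configuration switch. L_p^l is the generalized Laguerre polynomial with
degree p and order l (the Laguerre–Gauss beam convention). With q=2 the
identity LG(r=0) = −LG(r=1) holds exactly for l ≥ 1, so pooling |response|
over r∈[0,1] covers a half rotation, which is all that is needed.

Kernels are scaled to unit L2 norm before correlation: the raw formula
spans several orders of magnitude across the bank, and unnormalized
responses dominate the variance-based PCA, drowning the other families.
Features are computed per band (not on a luminance image). Rotation
invariance is exact on the enumerated grid: a quarter-turned patch yields
identical pooled maps up to the one-column shift induced by the even
kernel's anchor (verified to machine precision in the tests; the
acceptance checks use a 5% tolerance).

The "without spatial features" arm keeps only the intensity family; Sobel,
SSV and LG all count as spatial (configurable).

## Reduction, classifiers, cross-validation

PCA retains the minimal leading set of components reaching 99% cumulative
explained variance; it is refit inside every leave-one-out fold so the
projection never sees the held-out animal (`pca_scope='global'` reproduces
the laxer single-fit variant). Training rows are then subsampled uniformly
at random; the study-scale default is 1%. The desk-scale benchmarks use
5%: at 64×64 px with ~10 animals 1% would leave ~300 rows, far below the
~64k rows that 1% yields at full acquisition scale, so 5% (~1.3k rows) is
the closer analogue.

Classifier hyperparameters: RF — 400 trees, min leaf 3; AdaBoost — 400
depth-1 stumps, learning rate 0.1; RobustBoost — 100 stumps, error goal
0.2; SVMs — standardization, automatic kernel scale. The SVM "outlier
fraction 0.05" is mapped to the ν-SVM budget of margin violations
(ν=0.05); when classes overlap more than that budget allows, the ν-problem
is infeasible and the fit falls back to a standard C-SVM (logged).

RobustBoost is implemented from the boost-by-majority formulation: virtual
time t∈[0,1], margin weights w(m,t)=exp(−(m−μ(t))²/σ²(t)) with
μ(t)=(θ−2ρ)e^{1−t}+2ρ and σ²(t)=(σ_f²+1)e^{2(1−t)}−1; ρ is set so the
initial potential of a zero-margin example equals the error goal. Each
step trains a stump on the current weights and solves for a margin step α
(zeroing the stump/weight correlation, by bracketed root-finding) and a
time advance Δt (largest step that does not increase the average
potential, by bisection). The per-iteration time advance is capped at
0.05: on easy data a single strong stump can otherwise satisfy the
potential goal immediately, ending the run with an ensemble of one.
Numerical failure of the solve falls back to AdaBoost with a warning.

Seeds: one master seed; per-fold and per-classifier streams derive from
`SeedSequence(seed, spawn_key=(fold, k))`, making runs bit-reproducible.

## Evaluation

ACC, Sen, Spe, ACC2=(Sen+Spe)/2 and MCC come from per-fold confusion
counts; an empty Sen/Spe denominator yields 0 for that rate, and MCC with
any empty marginal is defined as 0 (the standard convention; it keeps fold
means defined). AUC is the Mann–Whitney rank statistic (ties ½), computed
on the pooled pixels of each held-out animal and then averaged over folds,
mirroring how the other metrics are aggregated; pooling over all animals
globally is available as an option. Final numbers are unweighted means
over folds, so every animal counts equally regardless of its pixel count.

The classifier × metric × spatial-features comparison is a three-factor
fixed-effects ANOVA on per-fold metric values (type-II sums of squares;
the design is balanced, where type II and type I coincide for main
effects), with partial η² = SS_effect / (SS_effect + SS_residual). A
factor with a single level is skipped; an exactly constant response
returns η²=0, p=1 directly.

## Benchmark conditions and what they show

Three desk-scale cohorts (64×64 px; lesion radii 8–12 px; margins,
specular spots and corner vignetting active) define the validation:

* **Strong contrast** (distinct lesion reflectance, noise SD 0.005): RF,
  AdaBoost and RobustBoost each reach mean LOO MCC > 0.8 — the pipeline
  recovers signal that is present.
* **Zero contrast** (identical reflectance and texture statistics, no
  vignette — a radial intensity profile would hand classifiers a position
  proxy because lesions never touch the border): every classifier stays
  within ±0.1 of MCC 0 — the pipeline does not hallucinate signal.
* **Texture contrast** (identical per-band means; lesion texture amplitude
  0.15 at 4 px scale vs. healthy 0.05 at 10 px): the spatial-feature arm
  beats the intensity-only arm in mean MCC for the classifiers tested —
  the spatial families carry real information. Lesion texture must be
  coarser than ~3 px to survive the two Gaussian passes (combined
  σ ≈ 2.2 px), which bounds how subtle a texture this condition can probe.

## Known limitations

* The reflectance levels, texture spectra and artefact models are
  schematic; no claim is made that synthetic accuracy levels transfer to
  tissue.
* The SSV family is an interpretation, not a reimplementation of its
  original definition.
* The ν-to-C SVM fallback changes the estimator family when the outlier
  budget is infeasible; runs record this in their warnings.
* Tile-wise MNF assumes noise statistics are locally stationary; tiles
  smaller than bands+2 pixels pass through untouched.
* The ANOVA treats per-fold metric values as independent observations;
  folds of one leave-one-out run share training data, so p-values are
  optimistic and should be read as descriptive.
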