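# Methods

## The problem and the data model

The package targets species-level identification of nine arable weeds from
laboratory VNIR hyperspectral imagery. The unit of acquisition is a
`SpectralCube` (lines × samples × bands, 400–1000 nm); the unit of
classification is an ROI — a set of at least 50 pure pixels from one
morphological part (leaf, stem, root, root collar, flower) of one plant.
The design cohort is 9 species × 25 plants with 2–3 ROIs per plant; the
reference survey's per-species ROI totals are imbalanced
(132/81/67/66/62/54/48/46/45, 601 in all) and the generator can reproduce
exactly that imbalance.

Because the original imagery is not publicly archived, the package ships a
synthetic-data generator as a first-class module: it emulates the
*statistical and spectral structure* of the survey, not its pixels, and
every downstream stage (calibration, preprocessing, PCA, metrics,
classification, evaluation) is exercised against it.

## Spectral model of the generator

Chlorophyll-bearing tissue is rendered as an additive composition

    R(λ) = base + A·exp(−(λ − 550)²/2σ_g²) + (R_NIR − base)·s((λ − c)/w)

with `s` the logistic function: a flat VIS baseline (chlorophyll absorption
in the blue and red), a Gaussian green peak at 550 nm (amplitude A,
σ_g = 25 nm), and a red-edge rise of centre `c` and width `w` from the VIS
level to the NIR plateau. The baseline is offset by the *analytic* average
of the green peak over 500–700 nm, so the clean curve's mean VIS
reflectance equals the species' nominal VIS level exactly — this keeps
cohort-level parameter recovery unbiased rather than approximately right.

Chlorophyll-free tissue (roots, root collars) is a bright 550–750 nm
plateau dropping into the NIR; white flowers are flat bright curves gently
declining past the red edge. Both families keep VIS ≥ NIR, as
amyloplast/lignin-dominated tissue does. Plateau geometry *inherits the
species' red-edge position* (rise centre 550 + 1.5·(c − 710) nm, drop
centre 738 + 2.5·(c − 710) nm): real root spectra still carry
species-specific micro-structure, and without this inheritance different
species' roots with equal brightness ranges would be mathematically
indistinguishable after scatter correction — an artefact of the shape
family, not a property of the system being emulated.

Species parameters: VIS/NIR levels are the survey's published values
(VIS 5–14 %, NIR 16–26 %). Red-edge centres are spread over 708–736 nm
(≈3.5 nm apart) within the 690–740 nm red-edge region, mimicking
chlorophyll-driven interspecific shifts in red-edge position; they sit
above ~708 nm so the sigmoid tail contributes negligibly to the VIS mean.
Part levels are anchored on the published per-part reflectance ranges
(plateau = part maximum, NIR tail = part minimum for bright parts). Stems
rise ~4 nm later than leaves; yellow flowers ~6 nm earlier and more
gradually (carotenoid, not chlorophyll, absorption).

## Variability model

Per plant: one multiplicative gain (sd 0.05), one additive offset
(sd 1.0 %), and a red-edge centre shift (sd 1.5 nm). Per pixel: a
multiplicative illumination gain (sd 0.05) and additive per-band sensor
noise (sd 0.5 %). A single global seed feeds a per-(species, plant) seed
sequence, so any plant regenerates in isolation and identical seeds are
bit-identical.

The red-edge jitter is the deliberate biological component: SNV removes
per-plant gain and offset *exactly* (it is affine-invariant), so without a
shape-level plant effect the classification task would be degenerate.
Defaults were fixed once, during generator development, against the
structure the survey reports: under them the per-species pixel PCA
concentrates 68–99 % of variance on PC1 (median 87 %, six of nine species
inside the reported 76–92 % span; the extremes are set by each species'
part-contrast structure, which global noise levels cannot move without
per-species tuning), and the classifier battery reproduces the reported
ordering (forest ≳ 90 %, SIMCA close behind, linear models intermediate,
small neural network worst).

What the generator does *not* emulate: spatial anatomy (plant cubes are
schematic stripes), mixed pixels and shadows, water-band structure, sensor
smile/keystone, or any SWIR (> 1000 nm) response. Passing tests therefore
demonstrate the correctness of the analysis chain and the plausibility of
the study design, not field-level performance.

## Processing chain

Calibration is the standard dark/white-reference form
`R = 100·(raw − dark)/(white − dark)`; bands where the references coincide
are flagged and set to missing. Reflectance is stored as float percent and
clipped to [0, 120] — real calibrations overshoot slightly on specular
facets, and the 120 cap preserves those flags for the specular-pixel mask
used at ROI extraction. Band lookup is nearest-neighbour (the native grid
is ~0.5 nm; interpolation would be needless).

Smoothing is a moving average with a shrunk (truncated) window at the
edges, default width 5 bands, followed by SNV with the population-σ
convention; the pipeline enforces this order. No band trimming is
performed anywhere in preprocessing; the 500–780 nm restriction happens
only inside the metrics layer.

PCA operates on mean-centred, unscaled reflectance (percent units are
homogeneous, so covariance — not correlation — is appropriate). Explained
percentages divide by the trace of the full band covariance, so they stay
well-defined when only k = 6 components are retained. Loading signs are
fixed by making each column's largest-magnitude element positive. The
score-plane density is a 100×100 histogram lookup, display-only.

## Spectral statistics

Per part, the primitive is (R_min, R_max, λ_min, λ_max) over the
500–780 nm operational window. Species-level statistics are the unweighted
arithmetic mean over all listed parts — including the whole-plant
"General" row when present — using the part midpoint for μ, the part range
for ΔR, and per-part wavelength metrics for SB, C, B_rel, C_norm. This
reconstruction is adopted because it reproduces the published species rows
from their own published part ranges (e.g. bindweed μ 22.6, ΔR 16.8,
SB 246.7, C 1.465) to the printed precision for every species except one
wavelength row (redroot pigweed SB prints 238.0 where the rule gives 250 —
treated as a typographic slip and excluded from golden comparisons).

σ, CV, the median and the rate of change R are computed from the same part
set by their textbook definitions but flagged `non-reconciled`: the
published values of those columns evidently derive from raw spectra that
part ranges cannot recover (e.g. printed CV ≠ printed σ/μ·100 for several
species), so they are reported for completeness and never used as
acceptance surfaces. For measured datasets the wavelength activity range
is detected as the span where the part's mean spectrum rises 5 % of its
dynamic range above its window minimum.

## Classifiers

Four algorithms stand on scikit-learn estimators at the study's
hyperparameters: Random Forest (100 trees, unrestricted depth, 11 features
per split — capped at the feature count when fewer), linear SVM (C = 1,
one-vs-rest; probabilities via softmax over decision values, a documented
approximation), a single-hidden-layer network with logistic activation and
width auto-selected as ⌈√(n_features · n_classes)⌉ (a documented default
where no rule is given), and maximum entropy as L2-regularised multinomial
logistic regression with per-sample λ = 0.001 (mapped to C = 1/(nλ); the
solver is interchangeable — any convex optimiser at tolerance counts).

SIMCA is implemented from scratch: per class, the training spectra are
centred and a PC1–PC2 basis extracted by SVD; a sample's orthogonal
distance to a class is the residual norm after projection onto that class
plane, and assignment is the arg-min (ties to the smaller class index).
A critical distance (mean + 3 sd of training residuals) is recorded per
class; probability-like scores are inverse-distance weights normalised to
sum 1. The implementation is verified against a brute-force
centre/project/residual oracle at 1e−10.

Validation is hierarchical: plants — never ROIs — are split 70/30 per
species (floor rule: 25 plants → 17/8), and cross-validation deals plants
to folds round-robin after a seeded shuffle, stratified by species, so no
plant straddles folds. Fold counts shrink with a warning when a species
has fewer plants than folds.

## Evaluation

Precision, recall and F1 are computed per class from the confusion matrix
(rows = true); degenerate classes (no predictions, or no true members)
report 0 with an explicit flag so macro averages stay defined. Macro
accuracy is the unweighted mean of per-class recall; micro accuracy is
trace/total, which equals overall accuracy for single-label problems and
is asserted on every report. Log loss uses the natural log with
probabilities clipped to [1e−15, 1]; log-loss reduction is
1 − model/prior, where the prior predictor emits the training class
frequencies. Algorithm rankings order by overall accuracy, ties by log
loss ascending.

## Problem sizes and numerical choices

Tests and the acceptance script run the cohort on a 61-band grid (10 nm
step over 400–1000 nm) with 60 pixels per ROI — the package's desk-scale
default; the full 1200-channel grid is available by configuration and
changes no interface. The end-to-end pipeline at these sizes completes in
well under a minute. Golden-table comparisons use ±0.1 for reflectance
quantities and SB, ±0.005 for the dimensionless wavelength ratios (the
printed precision); PCA is checked against its eigendecomposition oracle
at 1e−8; SIMCA against its projection oracle at 1e−10. Degenerate inputs
are rejected loudly rather than coerced: even smoothing windows,
zero-spread spectra for SNV, λ_min = 0 for the contrast ratio, orphan
plants at splitting.

## Known limitations

The generator's shape family is deliberately minimal (logistic + Gaussian
terms); it cannot represent double peaks, water absorption features or
senescent tissue. Per-part ROI counts within a species are drawn uniformly
over the species' part list (the survey does not report them). The
published 420/181 train/test ROI totals arise from the survey's particular
random plant draw and are not forced — only the 601 total is reproducible.
Classifier accuracies on synthetic cohorts characterise the pipeline, not
expected field accuracy.
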