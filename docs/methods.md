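# Methods

This note records the models, parameter choices, numerical details and
known limitations of the package, in the order data flows through it.

## Synthetic slide generator

**Textures.** Each of the six tissue classes is a parametric texture
(`TextureRecipe`): a background color, a nucleus color, a structural motif
(`blobs`, `rings`, `streaks`, `amorphous`), a density (elements per
10⁴ px²), an element radius (mean ± sd, px) and per-channel Gaussian noise.
The default palettes are H&E-plausible — purple nuclei on pink stroma,
red amorphous hemorrhage, pale streaked collagen, dense small lymphocyte
nuclei — and were chosen so the six class means are pairwise separable on
mean color alone (a nearest-centroid probe exceeds 99% on every pair; this
separability underwrites all classifier benchmarks). Rendering is a pure
function of `(recipe, size, seed)`.

**Slides.** A slide is a Voronoi mosaic inside a white border (16 px):
seed points are scattered uniformly, pixels are assigned to the nearest
seed, and cells are dealt greedily (largest cell first, to the class with
the largest remaining area deficit) so realized class fractions track the
request. The number of cells scales with area (one per 96² px), so the
request is met within ±5 percentage points from ~2048² up and more
coarsely on the small cohort slides. A per-pixel truth mask accompanies
every slide.

**Cohort heterogeneity.** Cohort slides (default 416×416 px, giving a 4×4
grid of 96-px tiles) draw their composition from a Dirichlet
(α = 2, 2, 1, 1.2, 0.8, 1.2 over TR, NLT, PA, FI, HNA, LA) mixed with a
25% uniform floor, so every class is present on every slide. Each slide
additionally perturbs a few recipe parameters, emulating biological and
staining variation between patients: tumor nucleus density and radius
(lognormal, σ = 0.35 / 0.15), lymphocyte density (σ = 0.35), fibrosis
noise (σ = 0.40), and the normal-liver background blue channel
(Gaussian, σ = 12). These jitters are deliberately independent, and each
feeds primarily one signature feature — that is what makes sparse-support
recovery by the LASSO a meaningful test rather than an exercise in
collinearity. A consequence of the uniform floor is that the six presence
flags are constant (all 1) on default cohorts; the model fitter detects
and drops constant columns automatically.

**Survival model.** Event times are Weibull proportional hazards
(default shape 1, i.e. exponential; scale 60 months):
T = scale·(−log U · e^(−lp))^(1/shape), with log-hazard
lp = Σⱼ βⱼ zⱼ over **z-standardized** signature columns. The default
planted coefficients are

| feature | β |
|---|---|
| `prop_TR` | +1.60 |
| `TR_blob_density` | +1.28 |
| `FI_glcm_contrast` | +0.96 |
| `LA_blob_density` | −1.28 |
| `NLT_mean_B` | −0.96 |

i.e. more tumor area, denser tumor nuclei and grainier fibrosis raise the
hazard; lymphocyte infiltration and a bluer (less eosin-shifted) normal
parenchyma lower it. The scale was calibrated once by simulation so that
the oracle linear predictor's Harrell C on the default cohort
(n = 600, seed 7) is ≈ 0.88, a discrimination level representative of a
strong histology score; it is then frozen. Only `prop_TR` is planted from
the proportion block: the six proportions sum to one, which is a constant
in a Cox linear predictor, so a support spread across all six proportions
would not be identifiable. Censoring is independent uniform on
[0, c_max], with c_max found by bisection so the realized censoring
fraction hits the target (default 30%) — the bisection uses the same
fixed uniform draws, so the whole cohort is a pure function of its seed.
Clinical covariates (age ~ N(54, 8), sex, AFP/ALT elevation, MVI, tumor
number and size) are independent draws with HCC-plausible prevalences;
they carry no hazard signal and exist to exercise the combined-score
plumbing, with no claim of realism.

**What the generator does not emulate.** Real nuclear morphology,
scanner artifacts, pyramidal resolution, spatially correlated tissue
architecture, and correlated clinical covariates. Tests passing on this
generator demonstrate that the pipeline's machinery is correct and that
its statistics behave as designed — not that the classifier or score
would reach the same numbers on clinical slides.

## Preprocessing

**Tissue mask.** Otsu threshold on the saturation channel after a
3-px Gaussian blur, with two robustness guards: (i) saturation is
compressed above 0.25 before thresholding — a strongly saturated class
(hemorrhage) otherwise makes the histogram multimodal and Otsu splits
tissue from tissue rather than tissue from glass (measured: Jaccard vs
truth 0.22 uncapped → 0.996 capped); (ii) if the Otsu split separates
modes by less than 0.05 the channel is treated as unimodal and a fixed
floor of 0.08 is used (a wall-to-wall tissue scan is then all tissue); a
constant channel yields an all-background mask.

**Tiling.** Non-overlapping grid anchored at (0, 0), 0-based row-major
indices, half-open extents; partial edge tiles are discarded and tiles
with tissue coverage below 0.5 (configurable) are excluded.

**Stain transfer.** The Reinhard color-transfer in lαβ: RGB → LMS with
the published cone matrix, log₁₀ (LMS clamped at 10⁻⁶), then the
orthogonal decorrelating rotation. Statistics (mean, sd per channel) are
computed over **masked tissue pixels only** — adding white background to
an image provably cannot change its template, which is the property the
masking buys. Normalization z-scores tissue pixels with the source
statistics, rescales to the target's, inverts, and rounds to uint8;
background passes through untouched. Numerical footnotes: channel sds are
clamped at 10⁻⁶ (constant-color tissue); self-transfer reproduces the
input within 2 gray levels and a second pass is idempotent within ±1 on
> 95% of pixels (the residual is uint8 re-quantization dither); when the
target's statistics push source pixels out of the RGB gamut the clipping
compresses the reproduced sds — transferring between slides of disjoint
tissue content clips ~8% of pixels and costs ~1% of sd, while the
intended use (same tissue classes, different stain) stays within 0.5%.

**Balancing.** Minority classes are upsampled to the majority count with
dihedral-group transforms (rotations by 90° multiples and flips), sampled
without repeating a (tile, transform) pair until all 8 transforms of all
tiles are exhausted. Dihedral transforms are label-preserving for
histology, which has no canonical orientation.

## Tile classifier

The classifier is a pluggable interface over classical backends operating
on the 21 tile features (below): `forest` (default) grows a random forest
in increments of 50 trees (max 400) and stops when validation accuracy
has not improved by 10⁻³ for 3 rounds; `mlp` trains a small
standardized-input perceptron (64, 32) by epoch-wise `partial_fit` with a
25-epoch patience (its validation accuracy moves in long plateaus). Both
are deterministic given their seed. On the default benchmark
(600 tiles/class, 96 px) the forest reaches test accuracy ≈ 1.0 in under
a minute on one CPU — the synthetic textures are deliberately separable,
so the benchmark checks the pipeline, not deep-learning capacity.
Evaluation reports overall accuracy, a row-normalized confusion matrix
(zero-support rows flagged), and one-vs-rest precision-recall curves with
AUC by trapezoid over recall; the integration follows the curve path
rather than re-sorting by recall, because tied perfect scores otherwise
pair the prevalence endpoint with recall 1 and corrupt the area.

## Classification maps

`build_map` runs the model over the tile grid; excluded tiles are
background. `smooth_map` applies a 3×3 majority vote (background cells do
not vote; ties keep the original label) and then absorbs 4-connected
components smaller than 2 cells into their largest neighboring component.
Absorption order and neighbor ties are canonicalized by (initial
component size, first cell in row-major order), making the operation
well-defined independent of how components are enumerated. Window,
connectivity and minimum region are configurable. `top_k_tiles` returns,
per class, the k = 10 tiles whose (smoothed) label equals the class,
ranked by that class's probability with row-major tie-breaks; fewer than
k available is flagged, and selection being label-constrained is a
documented choice.

## Signatures

Per tile (21 features): mean/sd of R, G, B and of l, α, β (12); gray-level
co-occurrence contrast, homogeneity, energy, correlation and entropy at
distance 1, averaged over the four axis/diagonal directions, on a
32-level quantization of luminance (5); and nuclei-proxy statistics from
Otsu-thresholded dark blobs — count density per 10⁴ px², mean area, area
fraction, mean ellipse eccentricity from per-region inertia tensors (4).
The four-angle GLCM average and the moment-based blob statistics make the
whole vector exactly invariant under 90° rotations. Per slide
(138 features, catalogue `hs-catalogue-1`): 6 class proportions over
tissue tiles, 6 × 21 per-class means over that class's top-K tiles
(zero-imputed when a class is absent), and 6 presence flags. Proportions
are tile-label counts, so their resolution is 1/n_tiles — on a 4×4 grid
that quantization caps the correlation with ground-truth composition
around 0.88; a 6×6 grid exceeds 0.9.

## Risk model

`fit_lasso_cox` standardizes columns internally, obtains the L1 path from
scikit-survival's Coxnet (50 path points, `alpha_min_ratio` 0.01), and
selects λ by seeded, event-stratified K-fold cross-validation (default
10) on the partial-likelihood deviance, computed the glmnet way:
dev = −2·[PL_all(β₋ₖ) − PL_train(β₋ₖ)] with a Breslow partial likelihood.
Path points that some fold's solver does not reach are excluded from the
λ choice. Coefficients are returned on the original feature scale, so
scores are invariant to column rescaling. `lambda_ = 0` falls back to an
unpenalized Newton fit (Efron ties); the penalized path uses Breslow's
convention, which coincides with Efron on tie-free data such as the
simulated cohorts. The `lambda.min` rule is the default (configurable);
it selects generously, which suits support-recovery use.

`optimal_cutoff` evaluates the two-group log-rank χ² at every midpoint
between consecutive distinct scores within the 10–90% quantile bounds,
subject to ≥ 10 subjects and ≥ 2 events on each side; ties resolve to the
smaller cutoff. The sweep is a vectorized O−E/V computation over all
candidates at once (cross-checked against lifelines' log-rank exactly),
which also makes a permutation calibration of the maximally selected
statistic affordable (`n_permutations`). Note that the maximally selected
cutpoint is an argmax over many near-equivalent candidates: with two
well-separated score clusters the chosen cutoff occasionally sits just
inside a cluster edge, misassigning a handful of subjects while carrying
a statistically indistinguishable log-rank value — operationally the
split still recovers cluster membership for ≥ 95% of subjects.
`stratify` applies the strict `score > cutoff` convention for high risk.

## Survival evaluation

Kaplan–Meier (Greenwood band), two-group log-rank and Cox regressions
(Efron ties, Newton solver, Wald CIs; `uni` mode fits one model per
covariate) are delegated to lifelines. Harrell's C uses the package-wide
orientation *higher score = higher risk*; ties in the score count ½, and
the CI is a seeded bootstrap (default 1000) or a Noether-style proportion
approximation. Time-dependent AUC is the cumulative-cases /
dynamic-controls estimator with inverse-probability-of-censoring weights
from the censoring Kaplan–Meier (scikit-survival), which reduces exactly
to the plain ROC AUC of the event-by-horizon indicator when there is no
censoring. The calibration curve bins predicted risks by quantiles
(default quartiles, degenerate bins merged with a warning) and compares
the bin's mean prediction with 1 − S(h) from the within-bin
Kaplan–Meier. The NRI is the continuous (category-free) variant — no
arbitrary risk categories — with event status at the horizon handled by
IPCW (events weigh 1/G(T⁻), survivors 1/G(h), subjects censored before
the horizon dropped) and a seeded bootstrap CI.

Two relationships worth knowing when interpreting outputs: global C is an
average of the time-dependent AUC over horizons, so the two agree only
for weak effects and diverge (AUC above C) as discrimination grows; and
duplicating every subject leaves the Breslow partial likelihood's
maximizer exactly invariant but perturbs an Efron fit slightly, because
duplication turns every event into a tie pair.

## Pipeline

`run_end_to_end` chains generation → classifier → maps → signatures →
cohort → LASSO-Cox → evaluation, writes each stage's artifacts
(CSV/JSON/PNG), and records a manifest with SHA-256 checksums, stage
timings and a config hash that covers the computational parameters but
not the output location. Identical config + seed reproduces identical
checksums. All randomness in a run derives from the single config seed
via fixed offsets per stage.

## Problem sizes

The default benchmarks are desk-scale by design: 600 tiles/class at
96 px for classification, and 600 slides of 416² px (16 tiles each) for
the cohort. These sizes keep the complete test suite and the acceptance
script within minutes on a single CPU while leaving every statistical
property (separability, oracle concordance, support recovery,
discrimination floors) comfortably measurable.

## Known limitations

* Synthetic textures are separable nearly to ceiling; classifier metrics
  here are pipeline checks, not statements about clinical imagery.
* The signature catalogue is a defined stand-in of the same flavor
  (color, texture, morphometry, composition) as a clinical feature set;
  no claim is made that these 138 features match any particular published
  list.
* Reinhard transfer cannot preserve statistics carried by out-of-gamut
  pixels; strongly mismatched source/target content degrades sd
  reproduction by ~1%.
* No competing risks, no pyramidal slide formats, no GPU training.
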