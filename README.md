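# histoscore

Tile-based H&E slide classification and LASSO-Cox prognostic scoring, with a
fully synthetic six-class histology benchmark.

## The problem

After curative resection of early-stage hepatocellular carcinoma, roughly
half of patients relapse within five years, and routine clinical markers
(AFP, stage, microvascular invasion) rank patients only modestly well.
Whole-slide images of the resected tissue carry far more information than
the handful of features a pathology report records. This package implements
the full computational chain that turns a slide into a recurrence-risk
score:

1. **Tissue masking** — Otsu threshold on the (capped) saturation channel
   separates stained tissue from white glass.
2. **Tiling** — the slide is cut into non-overlapping square tiles
   (299 px in the original setting; 96 px in the desk-scale benchmark).
3. **Stain standardization** — a *masked* Reinhard transfer: per-channel
   z-scoring in the decorrelated log color space (lαβ), with statistics
   pooled over tissue pixels only, so background never biases the template.
4. **Tile classification** — six tissue categories: tumor region (TR),
   normal liver tissue (NLT), portal area (PA), fibrosis (FI),
   hemorrhage/necrotic area (HNA), lymphocyte area (LA).
5. **Classification maps** — per-tile labels smoothed by label-grid
   morphology (3×3 majority vote + small-component absorption), and the
   ten highest-probability tiles per class selected.
6. **Pathological signatures** — 138 named per-slide features: class area
   proportions, per-class color/texture/morphometry means over top-K
   tiles, and presence flags.
7. **Risk scoring** — a LASSO-penalized Cox proportional-hazards fit over
   the signatures. The **histological score** is the linear predictor

   HS(x) = Σⱼ βⱼ xⱼ,

   with λ chosen by K-fold cross-validated partial-likelihood deviance
   (the `lambda.min` rule). Adding clinical covariates (sex, age, AFP,
   ALT, tumor number/size) to the penalized design gives the **combined
   score** CS. Patients split into high/low risk at the cutoff maximizing
   the two-group log-rank statistic (a maximally selected rank-statistic
   cutpoint), with high risk defined by a strict `score > cutoff`.
8. **Evaluation** — Kaplan–Meier curves and log-rank tests, uni- and
   multivariable Cox regressions, Harrell's C, time-dependent
   (cumulative/dynamic, IPCW-weighted) ROC AUC, calibration against the
   within-bin Kaplan–Meier, and the continuous net reclassification
   improvement (NRI).

Because clinical slides cannot ship with a package, `histoscore.synthgen`
renders six visually distinct H&E-like textures with per-pixel ground
truth, composes them into Voronoi-mosaic slides, and simulates survival
cohorts whose log-hazard is a **known sparse linear function of the slide
signatures** (Weibull baseline, proportional hazards, uniform censoring).
Every downstream stage is therefore testable against ground truth, and
LASSO-Cox support recovery is a well-posed end-to-end check.

## Worked example

```python
import numpy as np
from histoscore import risk_model, surv_eval, synthgen

# 120 synthetic slides with heterogeneous composition and staining,
# survival outcomes from a sparse planted log-hazard, ~30% censoring
slides, X, cohort = synthgen.default_cohort(n=120, seed=7)
t, e = cohort["time"].to_numpy(), cohort["event"].to_numpy()

tr = np.random.default_rng(7).permutation(120)[:84]
te = np.setdiff1d(np.arange(120), tr)
fit = risk_model.fit_lasso_cox(X.iloc[tr], t[tr], e[tr], seed=7)
hs = risk_model.compute_score(fit, X)
print(f"selected {fit.n_nonzero} of {X.shape[1]} signatures at lambda.min = {fit.lambda_:.4f}")

c_tr, _ = surv_eval.harrell_c(t[tr], e[tr], hs[tr], ci=False)
c_te, _ = surv_eval.harrell_c(t[te], e[te], hs[te], ci=False)
print(f"Harrell C: training {c_tr:.3f}, hold-out {c_te:.3f}")

cut = risk_model.optimal_cutoff(hs[tr], t[tr], e[tr])
groups, counts = risk_model.stratify(hs, cut.cutoff)
stat, p = surv_eval.logrank_test(t, e, groups)
print(f"cutoff {cut.cutoff:.3f}: {counts['high']} high / {counts['low']} low risk, "
      f"log-rank chi2 = {stat:.1f} (p = {p:.2e})")
```

Output:

```
selected 14 of 138 signatures at lambda.min = 0.0931
Harrell C: training 0.868, hold-out 0.879
cutoff 3.507: 36 high / 84 low risk, log-rank chi2 = 129.5 (p = 5.34e-30)
```

The LASSO keeps a handful of the 138 candidate signatures (including the
planted ones); the resulting score ranks ~87% of usable patient pairs
correctly out of sample, and splitting at the optimal cutoff separates the
recurrence curves decisively.

There is also a CLI: `histoscore demo` runs the whole synthetic workflow
(tiles → classifier → maps → signatures → scores → survival report) into
an output directory with a checksummed manifest; `histoscore tile`,
`normalize`, `train`, `map`, `signatures`, `fit`, `score`, `cutpoint` and
`report` expose the individual stages.

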