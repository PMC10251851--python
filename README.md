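# slideattn

Weakly-supervised prediction of lymph-node metastasis (LNM) status from
H&E-stained whole-slide images of primary muscle-invasive bladder
cancer, via attention-based multiple-instance learning (MIL) — plus the
clinical and combined logistic classifiers such a slide model is
benchmarked against, and the statistics used to compare them.

**Who this is for.** Computational-pathology researchers who want a
self-contained, CPU-only, fully testable implementation of the
slide-to-label MIL pipeline: tissue segmentation and tiling, stain
normalization, pluggable patch encoders with autoencoder reduction,
gated-attention bag classification, attention heatmaps, and the
accompanying evaluation statistics (AUROC with fold CIs, DeLong's paired
test, contingency chi-squared). Because the real cohorts cannot ship, a
first-class synthetic-data module generates feature bags, toy slides
with ground-truth region masks, and clinical cohorts with known
generating coefficients, so every claim the package makes is checkable
offline.

## The model

A slide is a *bag* of patch feature vectors `h_k` with one binary label;
a positive bag is assumed to contain at least one positive patch. Gated
attention pooling

    a_k = softmax_k( wᵀ( tanh(V h_k) ⊙ sigmoid(U h_k) ) ),
    z   = Σ_k a_k h_k

yields a slide embedding `z` scored by a linear head, trained with the
binary smooth top-1 SVM loss

    L(s, y) = τ · log Σ_j exp( (α·1[j≠y] + s_j − s_y) / τ ),

Adam (lr 1e−4, ℓ2 decay 1e−5), early stopping, and patient-stratified
five-fold cross-validation. The attention weights `a_k` double as patch
importance scores and are rendered as diverging-colormap heatmaps. The
clinical classifier is a logistic regression on age, gender, pT stage,
lymphovascular invasion, and histologic grade; the combined classifier
adds the MIL slide score as one covariate, with out-of-fold scores and
shared folds to avoid leakage. See `docs/methods.md` for the full
specification of every component.

## Worked example

Train on synthetic MIL bags (100 bags of 50 instances, witness rate 0.1)
with five-fold cross-validation:

```python
from slideattn import (BagSimConfig, TrainConfig, auroc, auroc_ci,
                       crossvalidate, generate_bags)

bags = generate_bags(BagSimConfig(n_bags=100, bag_size=50, dim=10,
                                  witness_rate=0.1, seed=7))
cv = crossvalidate(bags, k=5, seed=0,
                   config=TrainConfig(max_epochs=120, patience=20))
fold_aucs = [auroc(g["score"], g["label"])
             for _, g in cv.scores.groupby("fold")]
mean, lo, hi = auroc_ci(fold_aucs)
print(f"SBLNP out-of-fold AUROC: "
      f"{auroc(cv.scores['score'], cv.scores['label']):.3f} "
      f"(95% CI {lo:.3f}-{hi:.3f})")
```

```
SBLNP out-of-fold AUROC: 0.988 (95% CI 0.981-0.999)
```

The pooled out-of-fold AUROC says how well bag labels are recovered from
bags whose only signal is a 10% witness minority; the CI comes from the
spread of the five fold-level AUROCs. Fitting the clinical classifier on
a synthetic cohort generated from known coefficients (LVI log-odds 1.0,
pT step 0.5):

```python
from slideattn.clinical import fit_logistic
from slideattn.synthetic import generate_cohort

cohort = generate_cohort(2000, {"LVI": 1.0, "pT_stage": 0.5,
                                "intercept": -2.0}, seed=3)
report = fit_logistic(cohort.patients)
print(report.table[["variable", "coefficient", "p_value",
                    "odds_ratio"]].round(3).to_string(index=False))
```

```
 variable  coefficient  p_value  odds_ratio
intercept       -2.086    0.000       0.124
      age        0.001    0.829       1.001
   gender        0.023    0.832       1.023
 pT_stage        0.476    0.000       1.610
      LVI        0.943    0.000       2.567
    grade        0.061    0.735       1.063
```

The generating effects (LVI 1.0, pT 0.5) are recovered within sampling
error while the null covariates stay near zero with large p-values —
the parameter-recovery check the cohort generator exists for. Finally,
the contingency analysis of top-attention patch histology classes
(stroma-dominated in node-positive cases versus tumor-dominated in
node-negative ones):

```python
from slideattn import chi_squared_2x2
stat, df, p = chi_squared_2x2([[336, 414], [16, 734]])
print(f"stroma-class contingency: chi2 = {stat:.1f} (df = {df}), p = {p:.3g}")
```

```
stroma-class contingency: chi2 = 380.1 (df = 1), p = 1.18e-84
```

A command-line interface mirrors the library
(`slideattn synth|tile|normalize|features|train|clinical-fit|evaluate|heatmap`);
run `slideattn --help`.

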