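# aminoscreen

Plasma free amino-acid ("aminogram") profiling for matched case-control
cancer screening, built around the design used for non-small-cell lung
cancer (NSCLC): each patient's 21 plasma amino-acid concentrations (μM)
are combined into a single multivariate discriminant score whose ability
to separate patients from matched healthy controls is judged by the area
under the ROC curve.

The package is aimed at biostatisticians and metabolomics researchers who
want a tested, reproducible implementation of this analysis chain — and a
calibrated synthetic-cohort generator to exercise it, since cohort-level
amino-acid data of this kind are rarely shareable.

## The analysis

1. **Synthetic cohorts** (`synthetic_data`). Patients (n = 141) and
   controls are drawn from multivariate normals whose 21 per-group means
   and SDs are calibrated to published NSCLC study-set values, with a
   block correlation structure (BCAA {Val, Ile, Leu} ρ = 0.7, aromatic
   {Tyr, Phe, Trp} ρ = 0.5, urea-cycle {Cit, Orn, Arg} ρ = 0.4, baseline
   0.2). Demographics, tumour stage and histology follow the published
   margins. Draws with a non-positive concentration are rejected; the
   underlying draw parameters are moment-corrected so the accepted
   cohorts hit the configured means/SDs exactly.
2. **Matching** (`matching`). Each case gets m = 3 controls with
   identical gender and smoking status within a ±5-year age caliper,
   greedy nearest-age without replacement — the strata for conditional
   inference.
3. **Profiling** (`univariate_pca`). Per-amino-acid Mann-Whitney tests
   and univariate ROC AUCs; standardisation
   z_ij = (x_ij − x̄_j) / population SD_j; PCA of the standardised pooled
   matrix; components kept by the Kaiser rule (eigenvalue > 1) and score
   significance; a variable contributes to a component when its squared
   loading exceeds 0.05.
4. **Model selection** (`selection`). Every amino-acid subset with at
   most six variables is fitted by unconditional logistic regression and
   scored by a leave-one-out cross-validated AIC,
   AIC_cv = −2 Σᵢ [yᵢ ln p̂₋ᵢ + (1−yᵢ) ln(1−p̂₋ᵢ)] + 2(k+1),
   where p̂₋ᵢ is the held-out prediction for subject i. The minimum-AIC
   subset wins (82,159 candidates for the full 21-variable pool).
5. **Conditional fit and scoring** (`clogit`). The selected panel is
   refitted by conditional logistic regression over the matched strata
   (matching factors conditioned out, no intercept). The discriminant
   score of a subject is the linear predictor xᵀβ̂ — the logit of the
   conditional-logistic function value — applicable to matched and
   unmatched subjects alike.
6. **Evaluation** (`evaluation`). Rank-statistic ROC AUC (ties get half
   credit) overall and within stage/histology subgroups, each patient
   subgroup scored against all controls of the same data set.

Under the default generator the six-variable reference panel
{Ala, Val, Ile, His, Trp, Orn} has a closed-form population AUC of
Φ(βᵀΔ / √(βᵀΣ_case β + βᵀΣ_ctrl β)) ≈ 0.826, which the fitted pipeline
reproduces empirically.

## Worked example

Run the whole pipeline on a fresh synthetic study (141 cases, a
4,000-control recruitment pool, 1:3 matching, selection over the PCA
contributor panel with k ≤ 3):

```bash
aminoscreen run --seed 7 --out demo-run
```

prints

```json
{
  "best_subset": ["Val", "Ile", "Orn"],
  "cv_aic": 482.07770737205067,
  "study_auc": 0.8227453347417132,
  "test_auc": 0.7851782511811446
}
```

Reading: the exhaustive search picked the branched-chain/urea-cycle trio
{Val, Ile, Orn} (cross-validated AIC 482.1); its conditional-logistic
discriminant score separates the 141 patients from their 423 matched
controls with AUC 0.823, and still reaches 0.785 on an independent
simulated test set (162 patients vs 3,917 controls) that played no role
in selection or fitting. `demo-run/summary.json` additionally records
the conditional coefficients with Wald p-values (all < 1e-5 here), the
PCA eigenvalues (5.61, 1.56, 1.37, 1.02, 0.96), the contributor panel,
and per-stage/histology AUCs (stage I 0.821, II 0.913, III 0.864,
IV 0.731 — discrimination does not depend on stage, as the generator
draws aminograms independently of stage).

Every stage is also available separately
(`aminoscreen simulate|match|profile|select|fit|score|report`) and as
library functions (`aminoscreen.generate_cohort`,
`aminoscreen.match_controls`, `aminoscreen.exhaustive_search`,
`aminoscreen.fit_conditional`, ...).

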