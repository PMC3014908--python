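# Methods

This note documents the statistical model behind `aminoscreen`, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## The screening model

A subject's aminogram is the vector x ∈ R²¹ of plasma free amino-acid
concentrations (μM): Thr, Ser, Asn, Glu, Gln, Pro, Gly, Ala, Cit, ABA
(α-aminobutyric acid), Val, Met, Ile, Leu, Tyr, Phe, His, Trp, Orn, Lys,
Arg. The screening index is a linear discriminant score s = xᵀβ̂ whose
weights come from a conditional logistic regression over matched
case-control strata. The chain is: select a small panel by exhaustive
search under a cross-validated AIC using the *unconditional* likelihood;
then estimate β̂ for that panel from the *conditional* likelihood

&nbsp;&nbsp;L(β) = Π_strata exp(x_caseᵀβ) / Σ_members exp(x_jᵀβ),

which cancels stratum-specific intercepts and with them the matching
factors (age, gender, smoking). Matching covariates are therefore never
entered as regressors. The score s is the logit of the conditional
model's case probability, so it extends unchanged to unmatched subjects
(test sets, external patient groups).

## Synthetic cohort generator

No subject-level data exist for this design, so the generator *is* the
study population:

- **Aminogram marginals.** Per-group means/SDs equal published NSCLC
  study-set values (e.g. Ile 84.3 ± 22.1 μM in patients vs 69.7 ± 17.5
  in controls; Orn 67.6 ± 19.7 vs 54.4 ± 12.3; His 77.3 ± 15.0 vs
  80.8 ± 10.7). These are exact population targets.
- **Joint distribution.** Multivariate normal on the raw μM scale. A
  log-normal alternative would guarantee positivity but change the
  printed moments' meaning; normality keeps them exact. Positivity is
  enforced by rejecting vectors with any non-positive coordinate.
  Because Glu's mean sits only ≈2.4 SDs above zero, naive rejection
  would bias Glu's mean by ≈ +0.5 μM and, through the correlations,
  every other column by ≈ +0.004 SD. The generator therefore draws from
  *moment-corrected* underlying parameters obtained by fixed-point
  inversion of the truncated-normal moment identities (own mean
  m + s·h(m/s) and variance s²(1 − z·h − h²), h = φ/Φ, plus first-order
  cross terms s·(R h) for means and ρ²-weighted variance losses). At
  n = 2×10⁶ the residual bias is below the Monte-Carlo noise floor
  (≲0.3 SE at n = 10⁵). The adjustment is only applied to columns with
  mean/SD ≥ 2; configurations truncated more heavily than that fail the
  generator's rejection-rate guard (>50% over ≥1000 draws) instead.
- **Correlation structure.** Within-cohort correlations are never
  published for this design, so any choice is an assumption. The default
  is biologically motivated blocks — BCAA {Val, Ile, Leu} ρ = 0.7,
  aromatic {Tyr, Phe, Trp} ρ = 0.5, urea-cycle {Cit, Orn, Arg} ρ = 0.4 —
  over a baseline ρ = 0.2, shared by both groups. This induces the
  suppressor behaviour seen in the reference panel (Val and Trp carry
  almost no marginal effect yet help multivariately through their
  correlation with Ile/Tyr), and makes the six-variable reference panel's
  closed-form population AUC ≈ 0.826. Exact reproduction of any
  published eigenvalue/loading table is impossible under an assumed
  correlation structure and is not attempted; PCA checks are structural
  (trace, orthonormality, reconstruction) plus recovery of the
  *configured* population spectrum.
- **Demographics.** Age is truncated normal (resampling) within the
  published ranges: cases 62.7 ± 9.2 y on [34, 83]; study controls
  61.1 ± 8.7 y on [32, 82]. Gender, smoking (never/ex/current; unknown
  categories dropped before normalisation), BMI, stage (I–IV =
  69/8/39/25 of 141) and histology (adeno/squamous/other = 100/36/4 of
  140) follow the published margins. Aminograms are independent of
  demographics and stage by default (the reference analysis found
  stage-independent discrimination); hooks for coupling exist via custom
  configs.
- **Matching pool.** A control pool drawn with the *study-control* age
  margins cannot support 1:3 matching at a ±5 y caliper in every seed:
  case ages reach 83 while that pool is truncated at 82, and both age
  tails starve in small gender × smoking cells (~10% of seeds fail).
  The default matching pool is therefore a designed recruitment pool:
  age uniform over the case range [34, 83], gender/smoking from the case
  margins, control BMI — control aminogram marginals throughout. With a
  4,000-control pool this matched all 141 cases in 300/300 seeds with a
  post-matching age SMD ≤ 0.005. Plain control cohorts (for univariate
  calibration) are unaffected.

**What passing tests show — and do not.** The synthetic cohorts emulate
published group-level moments and margins under an assumed Gaussian
block-correlation model with measurement noise folded into the marginal
SDs. They do not model HPLC-ESI-MS measurement error, fasting/diurnal
variation, covariate-linked metabolic drift (age, smoking, cachexia), or
non-Gaussian tails. Passing the suite demonstrates the *pipeline* is
correct and the design is *capable* of >0.8 AUC under these conditions;
it says nothing about the discriminating power on real patients.

## Matching

Greedy nearest-age matching without replacement: cases in seeded random
order; eligible controls share gender and smoking exactly and lie within
the caliper; the m with the smallest age difference are taken, ties
broken by a seeded draw. The caliper is not part of the published
design; ±5 years is the conventional epidemiological default and is
configurable. Optimal (network-flow) and propensity matching are out of
scope. Any case with fewer than m eligible unused controls aborts the
match run (listing the case ids) unless partial matching is explicitly
allowed. Subjects missing gender or smoking are excluded with a warning.

## Profiling

The standardisation divides by the *population* (divide-by-n) SD, as the
reference formula specifies; sample-SD standardisation would only rescale
loadings. PCA is the eigen-decomposition of the correlation matrix of
the pooled (cases + controls) standardised matrix; group differences are
then tested on the scores, per component, with the Mann-Whitney test.
Column signs are fixed by orienting each loading column so its
largest-magnitude entry is positive; published loading tables are
reproducible only up to column sign, so comparisons use |loading|.
Components are retained by the Kaiser rule (eigenvalue > 1) and kept if
their score test has p < α (default 0.05; the reference components were
all < 0.001). A variable contributes when its squared loading exceeds
0.05 (i.e. |loading| > 0.2236). Applied to the published reference
loading table this rule reproduces the printed PC1 and PC5 contributor
lists exactly and adds Asn to PC3 (|−0.269|² = 0.072 > 0.05 although the
printed list omits it) — the implementation follows the stated rule and
the test suite documents the discrepancy rather than reverse-engineering
the table's marking. Whether loadings were eigenvalue-rescaled before
thresholding is unstated; raw eigenvector entries are used.

The Mann-Whitney implementation uses U = #(x>y) + ½·ties, exact
permutation enumeration when min(n) ≤ 8 (ties handled exactly), and the
tie-corrected normal approximation with continuity correction otherwise;
it is cross-checked against scipy and an exhaustive relabelling oracle.

## Selection

"Fewer than seven variables" fixes k_max = 6. The candidate score is an
AIC computed from leave-one-out *out-of-sample* function values: each
fold literally refits on n−1 subjects (Newton/IRLS, warm-started at the
full-data fit, coefficient tolerance 1e-8, ≤100 iterations) and predicts
the held-out subject; the deviance of those held-out predictions plus
the usual 2(k+1) penalty is the score. Whether the original criterion
kept the penalty on top of the cross-validated deviance is ambiguous;
both variants are implemented (`penalty=False` drops it), and since the
penalty is a monotone function of subset size, the default keeps it.
Probabilities are clipped at 1e-12 before logs so a separated fold
cannot produce an infinite deviance silently; instead, any
non-convergent fold (separation, lost class) poisons its candidate with
AIC = +∞, which is conservative and deterministic. Ranking ties break by
smaller subset then lexicographic order, making the result independent
of evaluation order and worker count. Selection uses the unconditional
likelihood; the matched structure enters only at the final conditional
fit.

The full 21-variable search has 82,159 candidates ≈ 46M fold-refits at
study scale; it is supported but the pipeline's default pool is the PCA
contributor panel with k_max = 3 (a few hundred candidates, ~1 minute),
which is also the scale the test suite exercises.

## Conditional fit and evaluation

Newton-Raphson on the conditional log-likelihood with stable
within-stratum log-sum-exp, monotone step-halving, gradient tolerance
1e-8, ≤100 iterations; standard errors from the inverse observed
information; per-variable p-values are Wald χ²₁ (matching the reference
report's per-variable style), with likelihood-ratio p-values available
via `ConditionalFit.lr_pvalues`. A covariate with zero within-stratum
variance everywhere raises a no-information error naming it. The
implementation is cross-checked against statsmodels' ConditionalLogit
and against grid-search/pair-difference oracles.

AUC is the Mann-Whitney rank statistic (ties ½); the ROC curve itself
comes from scikit-learn. Subgroup AUCs score each stage or histology
patient subgroup against *all* controls of the same data set (no
sub-matching is described for the reference design); subgroups with
fewer than 3 patients are flagged low-n, empty ones are reported as NA.
How a conditional model scores unmatched test subjects is not specified
anywhere; the linear predictor xᵀβ̂ is the only construction consistent
with "logit of the conditional-logistic function value" and is used for
all cohorts.

## Numerical and reproducibility choices

- All randomness flows from one run seed through named substreams
  (`substream_seed`: a Knuth-style multiplicative hash + CRC32 of the
  stream name, kept below 2³¹).
- Identical (config, seed) → byte-identical cohort CSVs and summary
  JSON; the provenance block records a SHA-256 of the scientific config
  (output paths excluded), the seed and library versions.
- Logistic/conditional Newton solvers flag non-convergence rather than
  raise; searches surface it through ranking, fits through `converged`.
- Test-suite problem sizes: study scale (141/423) for matching,
  profiling and conditional fitting; 10 seeds for the headline AUC
  check; a 10-variable k_max = 3 pool (175 candidates) for the search;
  200 replicates × 500 strata for CI coverage; n = 10⁵ for generator
  recovery. These keep the full suite under ~2 minutes while leaving
  every statistical tolerance at its stated value.

## Known limitations

- The correlation structure is an assumption; conclusions that depend on
  the specific block pattern (e.g. which suppressor variables get
  selected) are generator properties, not biology.
- Greedy matching is not optimal matching; with adversarial pools it can
  fail where an optimal assignment exists.
- Exact conditional inference (exact logistic p-values) and robust
  variances are not implemented.
- The exhaustive search is exact but O(Σ C(p,k))·O(n) refits; it is not
  a general feature-selection tool for large p.
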