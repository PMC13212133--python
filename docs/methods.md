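# Methods

`circamasld` reimplements, end to end, a cohort analysis linking disruption
of the rest–activity circadian rhythm to metabolic dysfunction-associated
steatotic liver disease (MASLD) and to a plasma-protein biomarker panel.
Because the real cohort (wrist accelerometry, clinical labs, and a
~3,000-protein plasma proteome) is access-restricted, every stage is driven
by a synthetic-cohort generator with planted ground truth, and the tests
check that each stage recovers what was planted.

## Rest–activity metrics

A participant's activity is summarised as 24 hourly mean accelerations
(arbitrary milli-gravity-like units). M10 and L5 are the means of the most
active 10-hour and least active 5-hour windows; the search is circular over
all 24 start hours, so L5 may span midnight (a non-wrapped search would
bias L5 upward, since the least active block typically straddles the date
line). Relative amplitude is

    RA = (M10 − L5) / (M10 + L5) ∈ [0, 1],

scale-invariant and strictly decreasing under additive shifts. Ties in the
window search are broken by the smallest start hour. The "low RA"
(disrupted-rhythm) group is everyone more than 2 sample standard deviations
below the cohort mean RA, with a strict `<` comparison so boundary cases
stay "high".

## Phenotyping

Hepatic steatosis is inferred from the fatty liver index,
FLI = 100·σ(0.953 ln TG + 0.139 BMI + 0.718 ln GGT + 0.053 WC − 15.745),
with TG in mg/dL and GGT in U/L (the coefficients are unit-bound;
converters from mmol/L are provided, ×88.57 for TG). FLI ≥ 60 defines
steatosis. MASLD is steatosis plus at least one of: type-2 diabetes,
BMI ≥ 25, or ≥ 2 items from a metabolic-abnormality list (insulin
resistance, prediabetes, low HDL and high waist circumference with
sex-specific cutoffs, hypertriglyceridemia ≥ 1.7 mmol/L, hypertension or
antihypertensive use). Unknown insulin resistance counts as not-met, so
the criterion count is conservative toward non-MASLD. The composite sleep
score awards one point each for morning chronotype, 7–8 h sleep, no
insomnia, no snoring, and at-most-occasional daytime sleepiness; scores
≥ 4 / 2–3 / ≤ 1 map to healthy / intermediate / poor patterns.

## Association layer

The 2×2 low-RA × MASLD odds ratio uses the Wald construction:
OR = ad/bc, SE = √(Σ 1/cell), 95% CI = exp(ln OR ± 1.96·SE). The
Haldane–Anscombe +0.5 correction is applied only when a cell is zero, so
the headline OR from non-degenerate tables is exact. Multivariable models
are binomial GLMs with logit link fitted by IRLS (convergence when the
max coefficient change < 1e−8, 100 iterations cap); Wald standard errors
come from the inverse observed information. Rank-deficient designs raise
an error naming aliased columns (QR with column pivoting); diverging
coefficients raise a separation warning and mark the fit unconverged.
The adjustment ladder fits four nested covariate sets (none; age+gender;
+education, ethnicity, deprivation index; +glucose, drinking, smoking)
with categorical covariates dummy-coded against fixed, configurable
reference levels (female / College / White / Never). Baseline tables use
one-way ANOVA for continuous rows and Pearson chi-square (no continuity
correction) for categorical rows. Missing covariates are imputed by
median (continuous) or mode (categorical, lexicographic tie-break), with
audit indicator columns.

The IRLS core is implemented in-repo rather than delegated: the mediation
bootstrap refits tens of thousands of small GLMs and per-fit overhead
dominates; the implementation is cross-checked against statsmodels GLM in
the test suite.

## Differential abundance with variance moderation

Each protein gets a two-group pooled-variance linear model (mean
difference `log_fc`, pooled residual variance s²_g, df = n − 2). The
empirical-Bayes step places a scaled inverse-chi-square prior on the true
variances and estimates its parameters (d0, s0²) by matching the first
two moments of ln s²_g through the digamma/trigamma equations; each
variance is replaced by the posterior mean

    s̃² = (d0·s0² + df·s²_g) / (d0 + df),

and the moderated t statistic log_fc / √(s̃²(1/n1 + 1/n2)) is referenced
to t with d0 + df degrees of freedom. When the observed variances show no
excess spread, d0 is capped at 1e6 and s0² falls back to the raw-scale
mean variance. The implementation reproduces Bioconductor limma's
`eBayes` (d0, s0², t, p) to ~6 decimal places on a shared fixture; that
cross-check runs as a regular test via Rscript. P-values are
Benjamini–Hochberg adjusted (configurable to Bonferroni through
statsmodels); proteins with adjusted p < 0.05 in both the low-RA and the
MASLD contrast form the common DEP set. Proteins with > 20% missing
values are dropped; remaining gaps are mean-imputed per protein.

## Mediation

For each candidate protein: a linear mediator model
(protein ~ exposure + covariates) and a logistic outcome model
(MASLD ~ exposure + protein + covariates). Counterfactual mediator values
per participant are the fitted mean under each exposure arm plus the
participant's observed residual; outcome probabilities are predicted
under the four exposure × mediator-regime combinations and averaged. The
average causal mediation effect (ACME) and average direct effect (ADE)
are each averaged over the two exposure arms, which makes the
decomposition exact: total = ACME + ADE to machine precision, on the
outcome-probability (risk-difference) scale. Uncertainty is a
nonparametric bootstrap over participants (percentile intervals); the
ACME p-value is the two-sided percentile p, floored at 1/n_boot.
Per-protein seeds derive from a root seed plus the protein index, so
enlarging the candidate list never perturbs earlier estimates. The screen
keeps proteins with ACME p < 0.05 and proportion mediated
(ACME/total, at the point estimates, deliberately unclamped) > 0.10.

Two properties of this estimator are worth knowing:

* **One-at-a-time bias.** When several correlated mediators share the
  exposure, the single-mediator outcome model is misspecified and the
  per-protein ACME systematically exceeds the structural per-protein
  effect (the omitted sibling mediators load onto the modelled one). On
  the default synthetic cohort the gap is roughly +0.03 on the
  probability scale. `synth.planted_acme` computes the structural ACME by
  g-computation on the true generating equations, so the divergence is
  measurable; recovery tests therefore compare bootstrap intervals with
  the estimator's own large-sample value (computed on a 120,000-participant
  cohort with identical structural parameters), which is the quantity the
  estimator is consistent for.
* **Null calibration.** With no exposure→mediator path (a = 0) but a live
  mediator→outcome path, ACME p-values are uniform (KS p ≈ 0.96 over 500
  null proteins). At the double null (a = b = 0) the product-path
  bootstrap p is conservative — a well-known property of mediation tests,
  not an implementation artifact. Percentile intervals also undercover
  mildly below n ≈ 1000; interval-based tests use n ≥ 1500.

## Panel selection and evaluation

Candidates passing the mediation screen enter an L1-penalized logistic
regression. The solver is glmnet-style: coordinate descent on the IRLS
quadratic surrogate, warm-started along a 100-point log-spaced lambda grid
spanning four decades down from lambda_max = max_j |x_jᵀ(y − ȳ)|/n (the
smallest penalty that zeroes every coefficient). Features are standardized
internally; the intercept is unpenalized. Lambda is chosen at the minimum
mean 10-fold cross-validated binomial deviance with outcome-stratified
folds (fold assignments stored for audit). The solver matches an
independent proximal-gradient (ISTA) oracle and sklearn's liblinear on
shared fixtures; the exact penalized objective is recorded per outer
iteration and is monotonically nonincreasing. (Within an outer step the
inner sweeps minimize the quadratic surrogate, which need not decrease
the exact objective sweep-by-sweep — only the per-outer-step trace is a
guaranteed descent quantity.)

Nonzero proteins are ranked by decreasing |standardized coefficient|
(ties: lexicographic). For each k, an unpenalized logistic model on the
top-k proteins is fitted on the 70% stratified training split and scored
by AUC on the held-out 30%; the panel is the smallest k whose AUC is
within 0.01 of the curve maximum. Evaluating the curve on the held-out
split (rather than training CV) avoids optimism. The final panel is then
evaluated with four classifiers — in-repo logistic regression, random
forest and RBF support-vector machine (scikit-learn; the SVM's
probabilities come from Platt-style sigmoid calibration on internal
training folds), and gradient-boosted trees (xgboost). ROC/AUC uses the
Mann–Whitney U statistic with midrank tie handling; curve points
threshold at each distinct score, so the trapezoidal area equals the rank
AUC exactly.

## Enrichment and network context

Functional context is strictly offline: gene-set collections are GMT
files and interaction networks two-column TSV edge lists, both
user-supplied, so results are reproducible against a pinned database
snapshot. Over-representation is the upper-tail hypergeometric p,
P(X ≥ overlap), BH-adjusted across sets; depletion is not computed.
"Core" proteins are the top 10% of nodes by degree (k = ⌈0.10·|V|⌉),
including all nodes tied with the k-th degree; self-loops and duplicate
edges are dropped.

## Synthetic cohort generator

The generator emulates the statistical shape the pipeline assumes, not
any real participant data:

* **Activity.** Hourly profiles follow a clipped cosinor
  max(0, mesor + A·cos(2π(h − φ)/24) + ε). Defaults: mesor 25, acrophase
  14 h, Gaussian noise SD 2. Amplitudes come from a two-regime mixture —
  a small disrupted group (fraction 0.037, matching the observed low-RA
  share) centred at the low end of `amplitude_range` (16, 24) and the
  rest at the high end, both with SD 1.5 — producing an RA distribution
  with mean ≈ 0.87, SD ≈ 0.06–0.08 and a low tail, the shape the
  mean − 2·SD rule expects. Clipping at zero slightly attenuates RA at
  high amplitude (acceleration cannot be negative).
* **Exposure.** The latent disruption exposure is continuous — the
  standardized negative noise-free RA — so the binary low-RA label the
  pipeline constructs is a coarsening of a real signal, as it is in
  practice.
* **Proteome.** Planted mediators (default 18, the size of the published
  panel) satisfy M_j = a·E + ε_j with a = 0.5 abundance units per
  exposure SD; per-protein noise variances follow a scaled
  inverse-chi-square (d0 = 8, s0² = 1), giving the moderation step a real
  prior to recover. The remaining proteins are independent of exposure
  and outcome given covariates.
* **Outcome.** MASLD is Bernoulli with
  logit = intercept + c·E + Σ_j b_j·M_j + covariate effects
  (c = 0.3, b = 0.4 per mediator, intercept −1.6 giving ≈ 31%
  prevalence). Covariates (age, sex, BMI, lipids, blood pressure, sleep
  questionnaire items, …) are drawn independently with moments matched to
  the published cohort descriptives; correlations are not modelled, which
  is the main respect in which passing tests understate real-data
  difficulty (no confounding structure beyond what is planted).
* **Seeding.** One global seed expands into per-component substreams
  (covariates / amplitudes / profiles / proteome / outcome), so enlarging
  the proteome never perturbs the covariate or profile draws.

One deliberate tension: the default planted effects are strong enough for
well-powered recovery tests (18 mediators × b = 0.4 compound to a very
strong low-RA→MASLD association, crude OR in the hundreds), far stronger
than the modest association an observational cohort shows. Matching the
observational odds ratio would require per-protein effects too weak for
any planted-truth recovery check to be meaningful at desk scale. Numbers
computed on synthetic cohorts are therefore labelled `synthetic_*` in the
acceptance output and are not comparable to the published cohort's
association estimates.

## Problem sizes used by the checks

The test suite and acceptance script run everything at desk scale, chosen
as the smallest sizes at which each statistical claim is meaningful:
parameter-recovery mediation at n = 5,000 with 18 mediators and 500
bootstrap resamples against a 120,000-participant large-sample oracle;
null calibration over 500 proteins at n = 400 with 200 resamples; panel
recall on a 2,500 × 120 cohort; the end-to-end pipeline at 4,000 × 300.
The published cohort's headline numbers that are recomputable from its
printed tables (crude OR 2.61, CI [2.42, 2.81], percentage cells,
attrition sums) are recomputed exactly from those counts.

## Known limitations

* Covariates are mutually independent by default; planted mediation is
  linear with homoscedastic Gaussian noise; no batch or plate structure.
* The mediation screen inherits the one-at-a-time bias described above;
  no sensitivity analysis for sequential ignorability, no
  exposure–mediator interactions, single mediators only.
* FLI unit mismatches (mmol/L vs mg/dL triglycerides) cannot be detected
  from values alone; callers must state units.
* The 2-SD low-RA threshold is cohort-relative; groupings from different
  cohorts are not comparable.
* Only the logistic panel model serializes to the reloadable JSON used by
  the risk predictor; tree/kernel models are evaluated but not persisted.
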