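# circamasld

Pipeline for studying the link between rest–activity circadian rhythm
disruption and metabolic dysfunction-associated steatotic liver disease
(MASLD), and for selecting a parsimonious plasma-protein panel that
predicts rhythm-related MASLD risk. It is written for epidemiologists and
computational biologists who want the full analysis chain — actigraphy
metrics, phenotyping, association models, proteome-wide screening,
mediation, and machine-learning panel evaluation — as tested, reusable,
scriptable components that run without access to any restricted cohort.

## What it computes

**Relative amplitude (RA).** From a participant's 24 hourly mean
accelerations, M10 and L5 are the means of the most active 10-hour and
least active 5-hour windows (circular search, ties to the earliest start),
and

    RA = (M10 − L5) / (M10 + L5) ∈ [0, 1].

Low RA — more than 2 sample SDs below the cohort mean — marks a disrupted
rest–activity rhythm.

**MASLD phenotype.** Hepatic steatosis is FLI ≥ 60, where
FLI = 100·σ(0.953 ln TG + 0.139 BMI + 0.718 ln GGT + 0.053 WC − 15.745)
(TG mg/dL, GGT U/L); MASLD additionally requires type-2 diabetes,
BMI ≥ 25, or ≥ 2 metabolic-abnormality criteria.

**Association.** Wald 2×2 odds ratios, nested multivariable logistic
models (in-repo IRLS), baseline tables with ANOVA/chi-square tests.

**Proteomics chain.** Per-protein moderated t statistics with
empirical-Bayes variance shrinkage → BH adjustment → intersection of the
low-RA and MASLD differential sets → per-protein counterfactual mediation
(ACME, proportion mediated, bootstrap intervals; screen at ACME p < 0.05
and proportion > 0.10) → L1-penalized logistic panel with 10-fold
cross-validated lambda → coefficient-ranked incremental-AUC curve cut by
the parsimony rule (smallest panel within 0.01 AUC of the maximum) →
evaluation with logistic regression, random forest, gradient-boosted
trees and SVM on a stratified 70/30 split, scored by rank-statistic
ROC/AUC. Gene-set over-representation (hypergeometric, offline GMT files)
and degree-centrality hub detection supply functional context.

A synthetic-cohort generator (`circamasld.synth`) with planted
exposure→protein→outcome mediation paths drives all tests and examples;
see `docs/methods.md` for the model and its deliberate simplifications.

## Worked example

```python
from circamasld.assoc import ContingencyTable2x2, odds_ratio_2x2

# low-RA/MASLD, low-RA/non, high-RA/MASLD, high-RA/non group sizes
t = ContingencyTable2x2(a=1633, b=1387, c=24390, d=54020)
est = odds_ratio_2x2(t)
print(f"OR = {est.or_:.2f}, 95% CI [{est.ci_low:.2f}, {est.ci_high:.2f}]")
```

prints

```
OR = 2.61, 95% CI [2.42, 2.81]
```

— participants with a disrupted rhythm have 2.6 times the odds of MASLD
in this stratification. Generating a cohort and computing RA metrics:

```python
from circamasld import synth, actigraphy

cfg = synth.SynthConfig(n_participants=2000, n_proteins=100,
                        n_mediators=8, seed=7)
cohort = synth.generate_cohort(cfg)
ra = actigraphy.metrics_table(cohort.profiles)
print(ra[["participant_id", "m10", "l5", "ra", "ra_group"]].head(3))
print(f"low-RA fraction: {(ra.ra_group == 'low').mean():.3f}")
```

```
participant_id       m10       l5       ra ra_group
       P000000 44.895852 0.527696 0.976766     high
       P000001 42.718522 3.793497 0.836881     high
       P000002 43.216716 3.201075 0.862075     high
low-RA fraction: 0.037
```

The full chain — generation, actigraphy, phenotyping, association,
differential abundance, mediation, panel — runs from one config:

```
circamasld pipeline --seed 11 --out run/
```

Every stage writes flat CSV/TSV/JSON intermediates plus `manifest.json`
with seeds, thresholds, and before/after counts at each filter. A saved
panel model predicts risk for new samples:

```
circamasld predict --model run/panel_model.json --input proteins.csv
```

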