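# morbinet

Multimorbidity burden stratification, progression prediction, and directed
disease co-occurrence networks on longitudinal diagnosis records.

## The problem

Most adults accumulate chronic conditions over time, and healthcare systems
increasingly summarise that accumulation with population case-mix indices: a
patient's validated, grouped diagnoses are weighted by clinical complexity
and summed into a continuous morbidity index, and population percentiles of
the index (P50, P80, P95) cut the population into four risk strata — low,
moderate, high, very high. Two questions follow naturally for
epidemiologists and health-service planners:

1. **Who will transition to high complexity?** Given a patient's baseline
   state, what is the risk that their index first crosses the P80 threshold
   within a 10-year window, and which predictors carry that signal?
2. **Which conditions accumulate together, and in what order?** Across the
   cohort's temporally ordered diagnostic histories, which condition pairs
   co-occur more than chance predicts, which direction do they arrive in,
   and does the sequence typically complete before or after the patient
   becomes highly complex?

`morbinet` implements this analysis end to end on synthetic cohorts with
known ground truth (real population registries of this kind are access
restricted). The package provides:

- a **cohort simulator** (`morbinet.simulate`): discrete-time annual onset
  hazards varying with age and sex, absorbing chronic conditions, recurring
  acute ones, age-dependent death, and *planted* directed pairwise
  enrichments that give every downstream statistic a known truth;
- a **morbidity-index engine** (`morbinet.index`): diagnosis validation,
  grouping via a code map, a one-year activity window for acute groups,
  weighted summation, hierarchical morbidity-group assignment, and
  percentile stratification;
- **outcome and feature construction** (`morbinet.features`): first-passage
  detection of the low/moderate → high/very-high transition, three nested
  predictor sets (base: age + sex; complexity: + six longitudinal morbidity
  summaries; full-disease: + per-condition indicators), and a multi-state
  tabulation over {low/moderate, high/very-high, dead};
- **predictive models** (`morbinet.models`): GLM, random forest, neural
  network and XGBoost under a stratified 70/30 split with repeated 5-fold
  tuning inside the training partition, held-out AUROC/AUPRC, permutation
  importance, and dedicated-vs-general subgroup comparisons;
- **network analysis** (`morbinet.networks`): pair and triplet co-occurrence
  risk ratios, exact one-sided significance screening with Bonferroni
  correction, pre/post/mixed timing classification relative to each
  patient's transition, and the general-population and disease-centred
  network builders with GraphML/JSON export.

## The statistics at the core

For conditions A, B (and C) in a cohort of N patients, with N_A patients
carrying A and N_AB carrying both:

```
RR_AB  = O/E = N_AB · N  / (N_A · N_B)
RR_ABC = O/E = N_ABC · N² / (N_A · N_B · N_C)
```

A *directed pair* A→B counts patients whose first onset of A strictly
precedes their first onset of B (ties count toward co-occurrence only).
Pairs are screened with the one-sided exact hypergeometric tail probability
of the observed overlap and retained when more than 50 patients carry both
conditions and p < α/m for the m evaluated pairs (α = 0.05). The general
network takes the 30 most frequent directed pairs, then the 60 strongest
remaining risk ratios touching those diseases; disease-centred networks take
the 10 most prevalent co-occurring conditions around a central disease, then
the 20 directed pairs with the highest triplet risk ratios jointly with it.

## Worked example

```bash
morbinet run-all --n-patients 2000 --seed 7 --out demo_run
```

simulates a 2,000-adult cohort followed 2013–2022 (with 10 pre-baseline
history years), computes yearly index series and strata, detects
transitions, fits base and complexity models, builds the networks, and
renders `demo_run/report.txt`. With this seed the report reads, in part:

```
[baseline]
Risk strata:
  low: 1555 (77.75%)
  moderate: 318 (15.9%)
  high: 105 (5.25%)
  very_high: 22 (1.1%)

[transitions]
Eligible (baseline below P80, alive at end): 1783
Transitioned to high/very-high: 320 (17.9%)
```

Strata are cut on the end-of-study index distribution, so the end-of-study
split is 50/30/15/5 by construction while the baseline distribution is
skewed toward low risk — most patients start healthy and accumulate
conditions. Of the 1,783 patients below P80 at baseline and alive
throughout, 17.9% crossed into high/very-high complexity. The fitted models
(`demo_run/metrics.csv`) show held-out AUROC rising from 0.80 (age and sex
alone) to 0.88 (GLM) when the longitudinal morbidity predictors are added —
baseline morbidity burden, not demographics, carries the signal. The top of
`demo_run/pairs_top.csv` lists the most frequent co-occurring pairs
(anxiety–mood disorders, hypertension–metabolic disorders, ...), which
follow directly from the simulator's planted enrichments.

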