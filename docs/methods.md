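# Methods

This note documents the models, parameter choices and numerical conventions
behind `morbinet`, and what the synthetic cohorts do and do not establish
about real populations.

## Cohort simulator

The generator is a discrete-time annual-hazard model. For patient *i*,
condition *c* and calendar year *t*, onset occurs with probability

```
h = base_hazard_c · exp(age_slope_c · (age_it − 50)) · s_c(sex_i) · Π m_e
```

clipped to [0, 1], where `s_c` is `sex_multiplier` for women and 1 for men,
and each planted pair effect *e* with consequent *c* contributes its
multiplier `m_e` from the calendar year **after** its antecedent's onset.
Chronic, neoplastic and pregnancy-related groups are absorbing (one onset
per patient); acute groups may recur each year. Death is drawn first within
each follow-up year from an age-band hazard and is absorbing; the cohort is
alive at baseline by construction, and pre-baseline history years carry
onsets but no deaths. Onset and death days are placed uniformly within the
year. One uniform vector per patient is drawn for each decision in a fixed
schedule, so two configurations differing only in a hazard share the rest of
their randomness — this is what makes the prevalence-monotonicity property
testable.

**Defaults.** Follow-up 2013-01-01 to 2022-12-31 with 10 history years; age
bands 18–40 / 40–60 / 60–70 / 70–80 / >80 with baseline weights
0.475/0.351/0.109/0.054/0.011 and 51.8% women, the age/sex structure of a
southern-European adult regional population; annual death hazards
0.0005/0.003/0.01/0.04/0.12 by attained age band, giving roughly 90%
ten-year survival under that age mix. The default condition roster (14
groups) mirrors the conditions that dominate adult multimorbidity —
metabolic disorders, anxiety, hypertension, osteoarthritis, substance use,
diabetes, chronic kidney disease, mood disorders, thyroid disease, chronic
respiratory disease, neoplasms, pregnancy, plus two recurring acute groups —
with annual base hazards between 0.002 and 0.05, positive age slopes for
cardiovascular/degenerative disease and flat-to-negative slopes for
mental-health onsets. Planted directed enrichments encode well-established
sequential patterns (metabolic → hypertension 2.2, metabolic → diabetes
2.5, substance use → anxiety 2.0, hypertension → kidney disease 2.5, ...).
Complexity weights (0.2–3.0) rise with clinical severity; they are
configuration inputs, so all index values are weight-relative.

**What the simulator is not.** All distributional choices are synthetic
stand-ins: no real diagnosis vocabulary, no socio-economic or behavioural
covariates, no seasonality, no coding noise beyond the deliberately
implausible events that the validation stage rejects (e.g. pregnancy codes
for men), and independence of conditions except through the planted pair
effects. Passing tests demonstrate that the pipeline recovers known
mechanisms, not that its outputs describe any real population.

## Morbidity index and strata

Validated events are grouped through the code map; persistent groups
(chronic/neoplastic/pregnancy) are active from onset onward, acute groups
only within the half-open window (date − 365 d, date]. The index is the sum
of the active groups' weights (each group counted once). Morbidity-group
assignment is hierarchical: active neoplasia, then pregnancy, then
`chronic_k_systems` with *k* the count of organ systems among active
chronic groups, then recent acute illness, else healthy.

Validation rejects, in order of precedence: onsets before birth, onsets
outside the configured analysis period, onsets violating a group's age
range, and onsets violating a group's sex restriction; every rejection is
logged with its reason, and unmapped codes are dropped with a logged count.

Thresholds use linear-interpolation percentiles (50/80/95) and require at
least 20 reference values. Strata are lower-edge inclusive: low < P50 ≤
moderate < P80 ≤ high < P95 ≤ very high. The reference distribution is
configurable; the pipeline default is the end-of-study index of the cohort,
which makes the end-of-study split 50/30/15/5 by definition (up to ties in a
discrete weight sum) while baseline proportions are an empirical output.
Thresholds are computed once, not per calendar year: a single reference
distribution is what makes strata comparable across the decade. The
evaluation grid is January 1 of each follow-up year, so transition dates
have one-year resolution.

## Outcome and predictors

The endpoint is the first grid date at which the index reaches P80. The
primary analysis restricts to patients below P80 at baseline and alive
through follow-up; patients already at/above P80 at baseline are ineligible
rather than erroneous, and decedents are excluded from the primary analysis
but retained in the multi-state tabulation (dead as an absorbing third
state), which quantifies the survivorship restriction. Excluding decedents
underestimates progression — patients on the fastest trajectories die
earliest — and the multi-state table is the package's measure of that bias.

The complexity predictors are: number of chronic conditions at baseline,
years since the first and the most recent chronic onset, the index at
baseline, and the index evaluated at the first and at the penultimate
chronic onset dates. Patients with no chronic condition get 0 for all
time-since/index-at features (their `n_chronic` 0 marks the sentinel); with
exactly one chronic condition, the penultimate-onset feature is evaluated at
that single onset. Full-disease indicators cover groups with chronicity
class `chronic`; neoplastic groups contribute to the index but not to the
chronic count or indicators.

## Models

Learners: logistic regression, random forest (200 trees), a single-hidden-
layer (16-unit) perceptron, and gradient-boosted trees (150 rounds,
learning rate 0.1), all behind a standard-scaler pipeline. Hyperparameter
grids are deliberately small and fixed (GLM C ∈ {0.01, 1, 100}; forest
depth ∈ {4, 12}; perceptron α ∈ {1e-4, 1e-2}; boosting depth ∈ {2, 4}) and
searched by repeated stratified 5-fold cross-validation inside the training
partition only (default 3 repeats, configurable; the test suite and
acceptance script use 1 repeat to keep desk-scale runs short). Class
imbalance is handled by stratified splitting only. AUROC is the rank
statistic with ties counted one half, AUPRC the step-wise precision-recall
integral; variable contributions use permutation importance uniformly across
learners so the families are comparable. Dedicated models are fitted on
baseline-condition subgroups with prevalence above 1% and compared with the
general model on the same held-out subgroup rows.

## Networks

Pair statistics operate on first onsets per patient and long-term group
(chronic and neoplastic classes), including onsets recorded before baseline.
The significance screen is the one-sided exact hypergeometric tail (Fisher)
for positive association — exact at small counts and standard for
co-occurrence enrichment; the Bonferroni denominator *m* is the number of
pairs with at least one co-affected patient in the run. The count filter is
strict (> 50 co-affected patients by default) and counts co-occurrence, not
directed-sequence, patients (switchable). Tier-2 selection in the general
network ranks by the co-occurrence risk ratio with direction attached from
the dominant directed count; "adjusted risk ratio" ranking in the
disease-centred networks is the triplet risk ratio computed jointly with the
central condition.

Timing classification considers patients supporting the directed sequence:
a sequence completed before the patient's transition date is *pre*, one
started at/after it is *post*, one straddling it is *spanning*; patients who
never transition count as *pre* by default (their accumulation occurred
below P80; `never_transition="drop"` excludes them instead). A pair is
labelled pre or post when the corresponding fraction reaches θ = 2/3,
otherwise mixed. All top-k selections break ties by count, then risk ratio,
then lexicographic ids, making every network deterministic. Edge widths are
directed counts min–max normalised to [1, 10] (a single distinct count maps
to 10); node sizes carry end-of-study prevalence.

## Numerical conventions and degenerate inputs

- Percentile thresholds: NumPy linear interpolation; degenerate (all-equal)
  reference distributions collapse all three thresholds, sending everything
  to the extreme strata by the lower-edge-inclusive rule.
- Report percentages round half away from zero, matching how printed cohort
  tables are rounded.
- Risk ratios raise on zero margins; zero overlap returns 0.
- Empty event sets produce index 0 and the healthy morbidity group.
- Seeds: every stochastic component (simulation, splits, tuning, shuffles,
  importance) takes an explicit seed and records it.

## Problem sizes

The test suite exercises cohorts of 800–20,000 patients; the acceptance
script uses 20 replicate 20,000-patient cohorts for the planted-enrichment
recovery, 100,000 scores for the strata split, and a 6,000-patient cohort
for the model comparison. These sizes give Monte-Carlo error well inside
the asserted tolerances while keeping a full run in the tens of seconds.

## Known limitations

- Weights are inputs, not estimated from outcomes; all index values and
  strata are relative to the supplied weight table.
- One-year outcome resolution: transitions within a year are dated to the
  next January 1.
- The simulator's independence-except-planted-pairs structure means triplet
  statistics are only exercised through overlapping pair effects.
- No calibration assessment of the models (discrimination only), matching
  the analysis scope.
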