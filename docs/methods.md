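# Methods

This note documents the models, defaults and design decisions behind
stratify-kit, and what the synthetic-data results do and do not show.

## Synthetic cohort generator

The generator emulates the statistical structure that risk-stratified
management relies on, not any particular health system's data.

**Event model.** Each patient-year, the probability of an acute-care
event starts at `base_event_rate` (default 0.06) shifted on the log-odds
scale by a per-physician effect drawn once per physician from
N(0, `physician_effect_sd`²) (default SD 0.5). Planted patterns —
conjunctions of conditions on the per-patient-year risk frame (age,
demographics, prior-year inpatient/acute counts, the physician's asthma
panel size, patient–physician distance) — then override the probability
(absolute mode) or scale it (multiplier mode), in list order so more
specific patterns win. The default plants "inpatient stay last year ⇒
0.45" and "inpatient stay last year AND physician has fewer than 10
asthma patients ⇒ 0.80": a prior admission is the dominant risk marker,
and a thin physician panel compounds it. Given an event year, the event
count is 1 + Poisson(0.3); each event becomes an acute encounter
(inpatient / emergency / urgent care at 0.35/0.45/0.20) with a primary
493.xx code and a lognormal cost with mean `event_unit_cost_mean`
($10,000, the order of magnitude of an admission).

**Cost model.** Annual non-event cost is lognormal with location
`7.0 + frailty_i` and within-year scale 0.9, where the per-patient
frailty is N(0, 1.3) and persists across years. The combined scale
(≈1.58 within a year) produces the cost pyramid: on 10,000 patients the
top 20% carry roughly 60% of multi-year total cost and about 77% of any
single year's cost, with the top 1% near 12% (multi-year) / 18%
(single-year). Persistence is what keeps multi-year totals skewed;
independent yearly draws would average the pyramid away.

**Other structure.** About 85% of patients truly have the chronic
disease; the rest receive no asthma codes or qualifying dispensings and
serve as negatives for cohort identification. Asthma patients receive
controller dispensings at a heterogeneous per-patient Poisson rate and
reliever dispensings whose rate rises with the true event probability.
Physician panels are skewed (Dirichlet(0.5) assignment weights) so some
physicians genuinely have small panels. Environmental series follow
`mean + station offset + seasonal sine + noise` for 21 variables
(PM2.5/PM10, CO, NO₂, SO₂, ozone, meteorology, and ten respiratory-virus
activity series) at 4 stations on a unit square; station offsets make
readings differ across stations. Missingness is injected completely at
random (default 2%) into optional patient cells; informative missingness
is out of scope. Dates are (year, month) pairs over an 11-year horizon;
geography is a unit square with Euclidean distance. All draws flow from
one `numpy` Generator seeded by `seed`, so bundles are bit-for-bit
reproducible.

**What passing tests do not show.** The generator's dependence structure
is a modelling choice: features are conditionally independent given the
planted patterns and physician effect, costs are exactly lognormal, and
coding is perfectly clean. Recovery of planted signal here demonstrates
correctness of the pipeline, not expected effect sizes on real EHR data,
where confounding, coding drift and informative missingness all bite.

## Cohort, outcomes and features

A patient enters the cohort with ≥1 diagnosis code in the 493.xx family
or ≥2 qualifying asthma-medication dispensings (inhaled steroids,
beta-agonists, leukotriene modifiers, other inhaled anti-inflammatories;
oral steroids excluded) within a one-year span. With month-resolution
dates the span test is "≤11 months apart", the conservative reading of
365 days.

Rows are patient × index-year; outcomes come from the following year
(binary acute-care outcome with primary 493.xx diagnosis; summed
reliever + oral-steroid refill amounts; total cost), so there is no
temporal leakage by construction, and permutation tests assert it.
Cohort members absent from next year's tables are labelled 0/0/0 —
absence of recorded care is treated as observable absence of events.

Patient features: age, demographics, prior-year visit counts by type,
prior-year acute-event count and cost, and the
controller-to-total-asthma-medication ratio (0.5 imputed when a patient
had no asthma medication that year, the neutral value). Physician-profile
features use the recorded primary physician (episode-grouper attribution
is out of scope): panel-composition counts as `log(1 + count)`
(normalizer 1 by default), the panel's leave-one-out mean outcome, mean
cost and mean controller ratio — with fallback to the population mean
when the leave-one-out panel has fewer than `min_panel = 5` patients —
the physician's own attributes, and patient–physician match indicators
(distance, same gender, same language, insurance accepted).
Environmental features are the yearly mean and max of each variable at
the station nearest the patient's home. Categorical features stay raw in
the matrix and are one-hot expanded at modelling time.

## Risk models

The learner registry (logistic regression, decision tree, random
forest, gradient boosting, k-NN; linear/ridge and tree ensembles for
cost) holds standard scikit-learn estimators; which learner is "best" is
an empirical question per dataset, so reports carry per-fold and pooled
metrics and selection is by CV metric. Minority oversampling interpolates
between a minority point and one of its 5 nearest minority neighbours,
is applied only to the training portion inside each fold (fold purity is
asserted), and errors below 2 minority rows. Backward elimination
greedily drops the attribute whose removal degrades the CV metric least
while staying within 0.02 of the full model, ties broken by attribute
name; shared fold seeds keep evaluations comparable.

The feature-merging reduction ranks features by absolute association
with the target (Pearson |r| for numeric, correlation ratio for
categorical; constants are excluded with a warning), keeps the top
`n_keep`, clusters the remainder by average-linkage agglomeration on the
distance 1 − |corr|, and replaces each cluster with the mean of its
standardized members. The added-value decision for physician-profile
features reads "higher accuracy by 10% or more" as an **absolute**
difference of 0.10 in AUC or R², consistent with the power statements
for a 0.1 AUC difference and a 10-point R² increment; a relative mode
sits behind a flag.

## Rule mining and explanation

Numeric features are discretized to half-open quantile bins (default
quartiles, outer bins open-ended so any value falls in exactly one bin);
low-cardinality and categorical features yield equality items; users may
override cut-points per feature, and per-feature constraints restrict
which values may appear in rules at all. Support uses the all-patients
denominator, which is why candidate itemsets can be counted over
high-risk rows only: the support numerator requires the high-risk label,
so frequency among high-risk rows alone decides the support threshold.
Equality of the restricted and unrestricted runs, and of the miner
against exhaustive enumeration, is asserted in tests.

Redundancy pruning drops a rule exactly when a strict sub-rule with at
least its confidence exists — the simplest member of the usual family,
and pluggable. Ranking is a deterministic total order: actionable rules
first, then confidence descending, support descending, fewer items, and
a canonical item-string as the final tie-break. Clinical review of rules
is modelled as a deny-list in the intervention registry, not automated.
Matching uses an inverted item → rule index; explanations return the
top-3 matching rules by default and may legitimately be empty (rare
reasons need not be covered). A patient's list is shown as ranked, with
no suppression of rules dominated by a displayed sub-rule.

At the defaults (support 1%, confidence 70%) a mild cohort can yield few
or no rules; the thresholds are exposed on the CLI rather than searched
automatically, mirroring how thresholds would be adjusted with clinical
review in the loop.

## Threshold optimization

Percentile granularity defaults to 100 equal-count bins; `c_e` is total
observed event cost over total events. Assignment is greedy per bin from
highest risk down among levels whose remaining capacity fits the whole
bin, minimizing `delta = c_i − avg_n_e·p·c_e`; ties go to the less
intensive (cheaper, then lower-p) level to conserve scarce capacity. The
implicit "no program" level (c_i = 0, p = 0, unbounded) guarantees
feasibility and anchors the no-enrollment comparator. Because a bin is
assigned as a unit, a program whose capacity is smaller than one bin is
never used — choose `n_bins` so capacities are at least a bin wide.
Without binding capacities the per-bin argmin is globally optimal
(verified against exhaustive enumeration); with binding capacities
greedy can be suboptimal, and the small-instance oracle measures the
gap rather than hiding it. The optional monotone pruning shortcut
(stop once every real program has positive delta on a bin it could still
accept) is exact when `avg_n_e` is non-increasing and is asserted
against unpruned runs. Stratifying by predicted cost instead of event
risk only changes the ranking variable; single-period optimization is
implemented, with no cross-period interaction of program effects.

## Outcome simulation

Two modes: *expectation* (deterministic; enrollment effects scaled by
the uptake fraction; used by default in tests) and *stochastic*
(Bernoulli uptake, binomial thinning of events, admissions and ED visits
by the avoided fraction p). Negative estimated costs — possible when
`n_e·p·c_e > h + c_i` — are floored at zero and counted, a corner the
cost formula itself leaves open. Aggregation restores input order so an
all-null policy reproduces baseline totals bit-exactly despite
float-addition order sensitivity. Sensitivity grids take 5 levels per
axis from the stated minimum to maximum (5×5×5 = 125 cells), with
thresholds re-optimized per cell. The fixed "heuristic pyramid"
comparator (top 1% case management, next 4% disease management, next 15%
supported self-care, rest wellness promotion) is a configurable default.
The minimum-accuracy search blends a calibrated predictor with
patient-wise uniform noise drawn once (so cost is a deterministic,
near-monotone function of the blend weight) and bisects for the point
where policy cost crosses baseline, reporting the AUC there.

Policy comparison uses a one-sided paired t test on `log(cost + 1)`
(the +1 admits zero-cost patients) and McNemar tests on paired
any-vs-none admission and ED indicators (dichotomization chosen because
the test is for paired binary outcomes; zero discordant pairs is
reported as non-informative rather than a p-value). Evaluating
rule-driven interventions reuses this simulator: registry entries carry
(c_i, p)-style parameters.

## Power calculations

`paired_t_sample_size` uses the normal-approximation paired design
`n = ⌈(z_{1−α} + z_power)² / d²⌉`, which gives 857 at one-sided α = .05,
power .90, d = 0.1 SD. `f_test_r2_power` uses the noncentral F with
Cohen's `f² = ΔR²/(1 − R²_base − ΔR²)` and noncentrality
`λ = f²(df1 + df2 + 1)`; the central F is used at λ = 0, where scipy's
noncentral implementation is unstable. `correlated_auc_sample_size`
inverts a two-sided z test with Hanley–McNeil exponential-approximation
AUC variances and covariance `2r√(V₁V₂)`, returning the smallest
per-class n by bisection. The companion design figures of 245 (R²
increment) and 137 per class (AUC difference) are **not** reproduced as
constants: the baseline R², the exact f² convention and the baseline AUC
pair they assume are not recoverable, so the functions expose every
assumption as an input instead of hard-coding outputs.

## Problem sizes used in checks

The shipped checks run on cohorts of 500–10,000 patients (10,000 where a
distributional claim such as the cost pyramid or planted-pattern
recovery is asserted; 1,200 × 6 years per replicate for the
physician-signal comparison), 50 random matrices for miner–oracle
equivalence, 100 random small instances for the optimizer oracle, and
200 replicates of 857 pairs for the paired-t power check — sizes chosen
so Monte-Carlo error is small relative to the asserted tolerances.

## Known limitations

- Generator realism: no comorbidity structure, coding noise, seasonal
  event timing within a year, or informative missingness; attribute
  count (~40 features) is far below a production EDW's, by design.
- The greedy optimizer has no optimality guarantee under binding
  capacities; the oracle quantifies the gap only on small instances.
- Rule mining is exhaustive within its thresholds; very low support
  thresholds on wide matrices grow the candidate space combinatorially.
- Single undesirable-event type, single-period policies, no discounting
  or inflation adjustment (a user-supplied deflator can be applied to
  cost columns upstream).
- McNemar comparisons dichotomize admissions/ED visits as any-vs-none;
  count-scale comparisons are not implemented.
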