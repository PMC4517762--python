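# Methods

## Setting and data model

The package operates on cross-sectional biopsy cohorts from PSA-based
early-detection programs: one record per man at the time of prostate
biopsy, carrying age (integer years, ≥ 18), total PSA (ng/mL), percent
free PSA (fPSA%, in [0, 100]), the biopsy outcome (benign/malignant),
the biopsy Gleason category for cancers (GS ≤ 6, 7(3+4), 7(4+3), 8, 9,
10, or missing), optional prostate volume, and — for men who proceeded
to radical prostatectomy — specimen pathology (Gleason category, pT
stage ≤ pT2c vs ≥ pT3a, margin R0/R1, each possibly missing). Benign
records never carry a Gleason category; malignant records may carry a
missing one. Ages stratify into four groups, ≤49 / 50–59 / 60–69 / ≥70
years, with inclusive boundaries as labelled; age at biopsy is treated
as floor-of-years.

## Decision rules

A rule assigns each age group a triple (t, c_low, c_high): biopsy is
indicated iff (fPSA% ≤ t and PSA ≥ c_low) or (fPSA% > t and
PSA ≥ c_high). Comparisons are inclusive on both axes, following the
printed forms of the cut-offs ("≥ x ng/mL", "fPSA ≤ 21%"); the
historical criterion printed as fPSA < 18% is honoured as a stratum
boundary placed at exactly 18, since no patient-level tie can be
resolved from summary data. c_high may be infinite (no biopsy above the
threshold). For fixed fPSA%, the indication is monotone non-decreasing
in PSA, and lowering any cut-off can only add flagged records.

How the historical criteria handled men with fPSA ≥ 18% is not fully
documented, so the historical constructor takes an explicit policy:

* `mirror_new` (default): borrow the revised scheme's 5/5/5/6 ng/mL
  high-fPSA cut-offs — the least inventive concrete pathway consistent
  with the historical scheme's reported 93–97% sensitivities, which
  rule out a blanket no-biopsy policy above 18%.
* `never`: infinite high-fPSA cut-off.
* `psa_only`: the same cut-offs in both strata, i.e. biopsy on elevated
  age-adjusted PSA alone. The historical scheme's reported
  specificities of 4–7.7% mean roughly 95% of *benign* men were
  biopsied, which only a PSA-alone trigger reproduces; this is the
  recommended comparator when emulating the historical-vs-revised
  biopsy-reduction analysis (see "Rule comparison" below).
* a custom four-vector of cut-offs.

## Diagnostics

Confusion matrices take the rule's indication as the test and malignant
biopsy as truth. Sensitivity, specificity, PPV and NPV are reported
with exact equal-tailed Clopper–Pearson intervals (beta quantiles; the
interval is the canonical "exact" choice and no alternative is offered,
to keep outputs comparable). A metric with a zero denominator is
reported as undefined (`None`), never as 0 — silently zeroing would
corrupt grid-search rankings. Predictive values in pipeline outputs are
always computed from raw counts; `predictive_values_from_rates` exists
solely as the documented bridge from *rounded published* rates to
published predictive values: tp = round(sens·n_mal),
tn = round(spec·n_ben) with ties away from zero, complements fill in
fn/fp, and PPV/NPV follow from the reconstructed counts. Percent values
in all report-style outputs are rounded half away from zero to one
decimal; IQRs use the linear-interpolation quantile definition; the SD
of a single observation is reported as 0 with a warning.

Tumor-recognition tables give, per age group and pooled, the flagged
fraction within each biopsy-Gleason category and each pT stage;
denominators exclude records missing the category, and empty categories
are reported as "no data" rather than 0%.

## ROC analysis

ROC curves of PSA for predicting malignant biopsy are empirical step
functions: thresholds sweep the distinct observed scores
(decision score ≥ threshold), tied scores contribute a single vertex
(diagonal segment), and (0,0)/(1,1) close the curve. AUC is the
trapezoidal integral, which under this tie handling equals the
Mann–Whitney statistic P(PSA_cancer > PSA_benign) + ½ P(tie). No
smoothing or binormal fit is applied. Curves are computed within fPSA
strata (≤ t vs > t for t = 18 or 21) per age group and pooled; a
degenerate stratum (empty or single-class) yields an absent curve with
a warning.

## Cut-off search

The scenario grid crosses PSA cut-offs 1.25–5.75 ng/mL in 0.5 steps
plus 6.0 (the sweep "between 1.25 and 6 in 0.5 increments" never lands
on 6.0, yet 6 ng/mL must be reachable because it is among the proposed
cut-offs), fPSA thresholds {15, 18, 21}%, and high-fPSA cut-offs
{5, 6, ∞} ng/mL, keeping combinations with c_high ≥ c_low — 90
scenarios per age group. The high-fPSA axis is a third dimension that a
two-axis sweep cannot span but the proposed dual cut-offs require; it
is configurable. Every scenario's full diagnostics are computed
exhaustively and deterministically.

Selection is per age group: scenarios whose own (not pooled)
sensitivity reaches the floor — default 0.88, the worst per-group
sensitivity of the historical rule — are feasible; among them the
winner maximizes lexicographically (specificity, PPV, NPV, lower
c_low). The published criterion "highest specificity and predictive
values" leaves the order unspecified; specificity-first operationalizes
the stated goal of avoiding benign biopsies, and the lower-cut-off
final key keeps sensitivity margin. Any residual tie breaks by (higher
fPSA threshold, lower c_high) so selection is a total order and
therefore invariant under permutation of the scenario list. Undefined
metrics rank below any defined value; a group with an empty feasible
set is reported infeasible explicitly. An audit trail records feasible
counts and the specificity margin to the runner-up.

## Rule comparison

Both rules are applied to the same cohort. Reported per group and
pooled: the flagged fractions, their difference (historical minus
revised), a 95% CI, NNS = 1/difference rounded to one decimal with the
CI obtained by reciprocating and swapping the difference CI endpoints
(a non-positive lower difference bound gives an infinite upper NNS
bound; a non-positive difference has no NNS), and a two-sided Fisher
exact p on the 2×2 table (flagged, unflagged) × (rule), point-probability
definition.

The default difference CI is the unpaired two-proportion Wald interval,
treating the two rule applications as independent margins. This
mirrors the conventional presentation in the screening literature the
package re-implements, but it is conservative: the two decisions are
made on the same men and are highly positively correlated. The paired
discordant-proportion interval is available via `ci_method="paired"`
and is the statistically preferable choice; it is typically several
times narrower for nested rules. The Fisher test inherits the same
independence idealization by construction.

## Synthetic cohort generator

Purpose: the patient-level data behind the published summary tables are
not available, so the generator emulates the *published* per-age-group
structure of a 2225-man screening biopsy cohort — sizes 178/597/962/488,
malignancy prevalences 34.3/49.4/54.5/69.3%, pooled PSA, fPSA% and
prostate-volume medians/IQRs, biopsy Gleason mix, and prostatectomy
pathology mix (a 758/1218 share of cancers carries specimen pathology).

Within a group, outcome is Bernoulli(prevalence). Conditional on
outcome, PSA is log-normal and fPSA%/100 logit-normal, independent
given status. The published tables pool benign and malignant cases, so
the status-specific locations and a shared within-group scale are
solved numerically (damped least squares on the mixture CDF) such that
the pooled mixture hits the published quartiles, with soft separation
targets fixing the benign/malignant split the tables do not determine:
P(PSA_mal ≥ historical low cut-off) ≈ 0.97 and P(fPSA_mal ≤ 18%) ≈ 0.90,
chosen once so that the historical rule's sensitivity on generated
cohorts lands in its reported 93–97% band. Sharing the scale parameter
within a group makes the malignant PSA distribution stochastically
dominate the benign one, which spec validation enforces. Quartiles, not
means, are the calibration targets: the published means (28.6 ng/mL
with SD 225 in the oldest group) are outlier-driven and unreachable for
a two-parameter log-normal; an optional heavy-tail component is
deliberately not included. Large-sample pooled quartiles of generated
cohorts match the targets within ±5% relative (tested).

Gleason categories are drawn for malignant records from the published
per-group mix, with the published "GS ≥ 8" mass split 70/25/5 over
GS 8/9/10 in the three older groups and left on GS 8 in the youngest
(whose published recognition tables contain no GS 9/10 cases); a small
published fraction has a missing category. Ages are discretized
truncated normals inside each stratum (upper bound 90 in the open-ended
group). One named generator stream per age group hangs off the single
global seed, so adding groups never reshuffles the others.

What the generator does **not** emulate: the selection effect that the
real cohort consists of men biopsied *because* they met the historical
criteria, which concentrates benign PSA above the historical cut-offs
and benign fPSA below 18% (reported historical specificities 4–7.7%);
PSA–fPSA correlation within status; PSA outliers; repeat screening
rounds; biopsy false negatives. Consequently, passing tests demonstrate
the correctness and determinism of the machinery on cohorts with the
published marginal structure — not that the synthetic grid search must
re-derive the published proposal, and absolute specificities and biopsy
fractions on synthetic cohorts differ from the published ones. This is
also why the historical-vs-revised reduction is emulated with the
`psa_only` comparator: under `mirror_new`, records with fPSA in
(18, 21]% and moderate PSA are flagged by the revised rule only, and on
independently drawn marginals the revised rule would *gain* biopsies,
contradicting the reductions reported in every age group, which imply a
PSA-alone historical trigger.

The planted-rule fixture (`separable_fixture`) sidesteps calibration
entirely: it places malignant blocks at the planted cut-offs and benign
sentinels just below them (with sub-grid-step jitter per seed) so that
on the scenario grid the planted rule uniquely attains sensitivity 1
and specificity 1, every deviation in any coordinate either drops a
≥ 1/3 malignant block below the feasibility floor (hence the floor must
exceed 2/3) or flags a benign sentinel. Grid-search recovery on these
fixtures is exact by construction and is verified across seeds.

## Numerical and degenerate-input conventions

* Rounding half away from zero (Decimal-based), matching clinical table
  typesetting; Python's banker's rounding is never used in reports.
* Infinite cut-offs serialize as `"inf"` in CSV/YAML outputs.
* Empty cohorts, single-class ROC inputs, zero-trial intervals and
  negative Fisher cells raise; empty comparison strata are omitted with
  a warning; the all-zero Fisher table returns p = 1 with a warning.
* Published reconstruction inputs live in `psascreen.reference`; two
  published inconsistencies are carried as-is and documented there: the
  50–59 historical-rule predictive values do not follow from their own
  rounded rates, and the 50–59 / 60–69 NNS values differ in the last
  decimal from the reciprocal of their printed reductions.

## Problem sizes used in tests

The default suite generates full-size cohorts (2225 records) where the
structure matters, 10^5-draw single groups for calibration checks,
200-record cohorts for brute-force oracle comparisons, exhaustive
(k, n ≤ 200) binomial-interval checks, and 300 random Fisher tables
with n ≤ 60 — sizes at which the independent oracles are exact and the
suite stays fast.
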