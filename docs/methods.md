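# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of the `worklife` pipeline.

## Measures

**Schedule classification.** A survey report of usual work timing maps to
one of five states by first-match precedence: not working → `NW`;
split/rotating/irregular flag → `VH`; start ≥ 6 a.m. and end by 6 p.m.
(same day) → `ST`; start ≥ 2 p.m. and end by midnight → `EV`; start ≥
9 p.m. *or* end by 8 a.m. (wrapping shifts allowed) → `NI`; anything else
→ `VH`. Precedence matters because the clock windows overlap (a
3 p.m.–5:30 p.m. shift satisfies both the standard and evening windows);
the order follows the order in which the definitions are conventionally
stated, from most to least standard. The night window is deliberately a
disjunction so that non-wrapping early-morning shifts (e.g. midnight–8
a.m.) count as nights; a conjunctive reading is ill-defined for them. An
end time equal to the start is read as a 24-hour wrap, except the
degenerate 0–0 report.

**Weekly sleep.** The default weekly per-day average is the unweighted
mean of the weekday and weekend reports, `(wd + we) / 2`: applied to
cohort means of 6.62 and 7.21 h it reproduces the published weekly mean
of 6.92 h, which the 5:2-weighted variant `(5·wd + 2·we)/7` (also
available, `formula="weighted52"`) does not (6.79). Missing inputs
propagate.

**Sleep quality.** Four 1–4 Likert items on sleep problems are reversed
(`5 − item`, so higher = better), averaged, and z-standardized over the
persons with complete items; the score therefore has mean 0 and SD 1
within the analysis cohort by construction, and differences are in SD
units. Averaging before standardizing (rather than summing) is
immaterial to the standardized result. Cronbach's alpha is reported
alongside. The survey instrument does not state the reverse-coding
direction beyond "higher is better"; the orientation here is a documented
package convention.

**CES-D.** The 7-item short form is the plain item sum (0–21), coded
missing if *any* item is missing, with the clinical-risk flag at ≥ 8.

**Poor health.** Self-rated general health 1 (excellent) – 5 (poor)
dichotomized at fair-or-poor (4 or 5).

**Exposure classifications.** Weekly-hours and occupation histories are
classified by proportions of observed years: full-time = 35+ hours; a
category wins at a share ≥ 0.50 (inclusive at exactly one half, in favor
of the named category); "about an equal share" (mixed) is operationalized
as no category reaching 0.50. Non-working (zero-hour) years are excluded
from the weekly-hours denominator — the survey text does not say whether
they count; excluding them is flagged here as the package's choice. Year
order never matters.

**Cohort filter.** Persons are dropped, in order and with per-rule
counts: missing the target outcome; entirely missing state sequence
(partial gaps are resolved by carry-forward, below); missing any model
covariate (listwise).

## Sequence analysis

**Distances.** OM edit distance via the standard `(|a|+1)×(|b|+1)`
Needleman–Wunsch dynamic program; indel cost 1; substitution costs from
the TRATE construction `s(i,j) = c − p(j|i) − p(i|j)` with `c = 2`, the
transition rates pooled over all persons and adjacent year pairs
(time-invariant costs; time-varying costs are out of scope). Costs are
clipped at 0 rather than erroring if the rates sum above `c`; entries
above `2·indel` trigger a warning because a delete+insert pair then
undercuts the substitution. Constant-cost matrices (e.g. 2 or 3) are
available for sensitivity analysis. Distances are not normalized by
length — all preprocessed sequences have the fixed length 28, so
normalization would only rescale.

**Missing states.** Resolved before distance computation by last
observation carried forward, with leading gaps back-filled from the first
observed state. This matches how biennial survey gaps are conventionally
expanded onto a yearly axis; the generator can emit either
observed-every-year or biennial-gap panels, and the gap-filled biennial
panel equals the fully observed one at the observed positions.

**Performance.** All-pairs distances run through a numba kernel with
identical-sequence deduplication (compute once per distinct pair,
broadcast); the result is bit-identical to the naive double loop, which
the tests verify. The condensed matrix memory is estimated before
allocation and a configurable limit raises early.

## Clustering and stopping rules

Ward linkage is delegated to scipy's nearest-neighbour-chain
implementation. On a condensed dissimilarity matrix scipy's `ward` *is*
the Ward.D2 convention (the Lance–Williams update on squared
dissimilarities, heights on the distance scale); the Ward.D variant is
exposed by running the same recursion on the square roots and squaring
the heights back, since the two conventions differ exactly by that
transformation. Merge order on ties follows scipy's deterministic chain
order, so runs are reproducible across platforms.

Both stopping rules are computed in distance-based form, which coincides
with the familiar variance form for Euclidean input (verified to 1e-8
against coordinate oracles in the tests):

- within-cluster sum of squares `W_c = (1/n_c) Σ_{i<j∈c} d²(i,j)`;
- Calinski–Harabasz `F = (B/(k−1)) / (W/(n−k))`, `B = T − W`, `+∞` for a
  perfect partition;
- Duda–Hart per candidate split down the tree (the hierarchical
  convention, not arbitrary 2-means splits): ratio `Je(2)/Je(1)` and
  `pseudo-T² = (Je(1) − Je(2)) / (Je(2)/(n₁+n₂−2))`.

The recommended `k` is the largest CH value among local maxima of the CH
curve, with the Duda–Hart ratio at the corresponding split reported as
corroboration and a low-confidence flag when the curve has no interior
peak. Substantive interpretability of clusters cannot be automated, so a
user-supplied `k` is never overridden; 5 is the documented default for
this design. Cut labels are relabeled deterministically by cluster size,
then first member index.

## Outcome models

Treatment coding against the published reference levels (pattern: stable
standard hours; race: non-Hispanic White; education: high school; weekly
hours: mostly full-time; occupation: mostly service). The design coding
is derived once from the estimation sample — validating that every
reference level is present — and then frozen, so margins can set every
row to a counterfactual level without the column set changing.

- **Robust covariance:** HC1, matching the common "robust" default behind
  reported robust-adjusted standard errors.
- **Intervals:** `b ± 1.96·se` (normal multiplier), matching the
  reporting convention rather than t quantiles.
- **Logit:** Newton MLE, relative log-likelihood tolerance 1e-10, max 100
  iterations; coefficients are reported on the log-odds scale with an
  odds-ratio column derived on output. Perfect or quasi separation is
  detected (drifting coefficients with vanishing score) and reported as
  an error naming the offending columns; in `fit_outcome`, sparse
  *interaction* cells that separate are dropped with a warning — they
  carry no estimable interaction term — as are all-zero columns from
  combinations absent in the data.
- **Wald contrasts:** single-df `χ² = (c'b)²/(c'Vc)` with the robust `V`;
  equals the squared z statistic for a single coefficient.
- **Margins:** average adjusted predictions over the estimation sample
  (not predictions at means; the at-means variant would change the
  reported quantity, and the predicted-estimates tables this mirrors are
  sample-averaged). For logit models predictions are on the probability
  scale and the delta-method gradient is `mean(p(1−p)·x)`. For linear
  models the share-weighted average of level predictions equals the
  overall mean prediction exactly — an identity the tests assert at
  1e-8.
- Interaction analyses cross the pattern dummies with one social-position
  marker at a time (gender, race-ethnicity, education), as in the source
  design; the margins grid is emitted for every pattern × marker-level
  combination with empty cells flagged (`n_cell = 0`). Whether
  predicted-estimate tables should come from the main-effects or the
  interaction models is ambiguous in the source; the pipeline computes
  both and labels them.
- No multiple-testing correction is applied (none is applied in the
  source design); interpret the many interaction contrasts accordingly.

## Synthetic-data generator

The generator emulates the *structure* the analysis assumes, not any real
sample's joint distribution:

- **Archetypes.** Five trajectory archetypes at shares
  10.74/11.52/17.11/34.80/25.83%: mostly not working; early standard then
  mostly variable hours (switch at 30); early standard then volatile
  (an evening/night/variable mix after 30); mostly standard with some
  variable hours; stable standard. Emission is sticky-Markov: each year a
  fresh draw from the per-age profile, or with probability `stickiness` a
  repeat of last year's state.
- **Stickiness is per-archetype** (0.70/0.45/0.25/0.15/0.55). The groups
  defined by schedule *stability* persist strongly; the volatile and
  variable-hours groups are defined by churn, so their stickiness is low.
  Besides realism, this matters statistically: high stickiness in a
  mixing group produces long accidental runs of a single nonstandard
  state, making two members of the same archetype look maximally distant
  under OM and smearing the cluster structure. With the defaults the
  archetypes are well separated: the pipeline recovers them with ARI
  ≳ 0.9 at n = 1,000 and the stopping rules recommend k = 5. A scalar or
  per-archetype override is accepted; a uniform 0.8 (heavily
  autocorrelated everywhere) is a plausible alternative for sensitivity
  work but leaves the mixing archetypes poorly separated by design.
- **Covariates** are drawn from archetype-conditional categorical/count
  distributions whose defaults follow the published per-pattern
  cross-tabulations (gender, race-ethnicity, education, weekly-hours and
  occupation categories, marriage/children/welfare/poverty counts,
  baseline age). Only marginal/cross-tab structure is modelled — no
  structural model between covariates, and no attrition/selection beyond
  missing-completely-at-random masking.
- **Outcomes** come from linear/logistic models with archetype effects on
  the published effect scale (e.g. −0.24 h sleep and +0.45 poor-health
  log-odds for the early-ST-volatile group vs stable ST) plus covariate
  effects and Gaussian noise. Item-level columns are emitted so the
  measures module derives the scales: weekday/weekend hours split ±0.295
  around the latent weekly mean (the observed weekday–weekend gap);
  sleep-quality items from a one-factor model with loading 0.80, chosen
  so the discretized 4-level items give Cronbach's alpha ≈ 0.84, the
  instrument's published reliability; general health drawn to be
  consistent with the latent poor-health indicator; CES-D totals
  allocated across the seven 0–3 items (a total of 21 forces all items
  to 3). Derived scales therefore recover the latent values exactly up to
  discretization.
- **Seeding.** One integer master seed; every operation draws from its
  own deterministically derived sub-stream, so identical (config, seed)
  gives byte-identical bundles and stages can be rerun independently.

What passing tests on this generator do **not** show: robustness to
informative attrition, to misclassified schedule reports, to real joint
covariate distributions, or to cluster structure weaker than the
well-separated default — on weakly separated data the stopping rules
legitimately recommend coarser solutions.

## Problem sizes

Default problem sizes were chosen so each piece demonstrates its property
at desk scale: n = 10,000 for law-of-large-numbers share checks, n = 1,000
for pipeline cluster recovery, n = 50,000 for single-run coefficient
recovery, 200 replicates at n = 2,000 for robust-CI coverage (90–98%
nominal band), and n = 4,000 for the narrative analysis scripts — large
enough that ~1% covariate categories retain events in the logistic fits.

## Known limitations

- OM with indel below half the substitution range means long
  insertions/deletions can dominate alignments; results are reported for
  the indel-1/TRATE configuration and constant-cost sensitivity variants,
  not a general cost calibration.
- The Duda–Hart table follows the tree's own splits; it does not evaluate
  alternative bipartitions.
- Logistic models with very sparse cells report or drop separated terms
  rather than penalizing; no Firth-type correction is implemented.
- SF-12 item-level scoring is out of scope: global physical/mental scores
  are consumed and generated directly on the mean-50/SD-10 convention.
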