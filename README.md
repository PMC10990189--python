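# worklife

Life-course analysis of work-schedule trajectories and midlife health.

Epidemiologists studying precarious employment ask how *patterns* of work
schedules over a whole career — not single snapshots — relate to sleep and
health in middle adulthood. This package implements that analysis end to
end for yearly employment states over ages 22–49, coded with the five-token
alphabet

| token | meaning |
|-------|---------|
| `NW`  | not working |
| `ST`  | standard hours (start ≥ 6 a.m., end by 6 p.m.) |
| `EV`  | evening hours (start ≥ 2 p.m., end by midnight) |
| `NI`  | night hours (start ≥ 9 p.m. or end by 8 a.m.) |
| `VH`  | variable hours (split / rotating / irregular) |

and health outcomes measured at age 50: weekly sleep hours, a standardized
4-item sleep-quality score, fair/poor self-rated health, SF-12
physical/mental function, and the 7-item CES-D depression short form
(0–21, clinical-risk cutoff ≥ 8).

## The method

1. **Sequence dissimilarity.** Optimal matching (OM): the edit distance
   between two state sequences `x`, `y` under insertions/deletions at cost
   1 and substitutions costed by the transition-rate ("TRATE") matrix
   `s(i,j) = c − p(j|i) − p(i|j)` with `c = 2`, where `p(j|i)` are pooled
   year-to-year transition rates — rare transitions cost more. Computed by
   the Needleman–Wunsch dynamic program.
2. **Clustering.** Ward's hierarchical agglomeration on the OM distance
   matrix (Ward.D2 convention), with the Calinski–Harabasz pseudo-F
   `F = (B/(k−1)) / (W/(n−k))` and the Duda–Hart `Je(2)/Je(1)` ratio with
   pseudo-T² as stopping rules for the number of patterns `k`.
3. **Outcome models.** OLS (continuous outcomes) and logistic (binary
   outcomes) regressions of each age-50 outcome on pattern membership
   (reference: stable standard hours) plus sociodemographic covariates,
   with HC1 robust standard errors; post-estimation Wald contrasts
   `χ² = (c'b)² / (c'Vc)` between patterns; and delta-method **average
   adjusted predictions** (margins): the sample-mean prediction with the
   focal variable set to each level, `se = √(g'Vg)` with `g` the gradient
   of the averaged prediction in the coefficients.

Because the motivating cohort data are restricted-access, the package
ships a first-class synthetic generator (`worklife.synth`) that emulates
the cohort's structure — five trajectory archetypes at realistic shares
(10.7/11.5/17.1/34.8/25.8%), sticky Markov state emission,
archetype-conditional covariates, and outcomes generated from
linear/logistic models on the published effect scale — so every stage is
testable without any download.

## Worked example

```python
import worklife as wl
from worklife import models

bundle = wl.generate_bundle(n=2000, seed=7)
panel = bundle.sequences.fill_gaps()
costs = wl.trate_costs(wl.estimate_transition_rates(panel), c=2.0, indel=1.0)
dm = wl.pairwise_distances(panel, costs)
tree = wl.ward_linkage(dm)
print(wl.cluster_solution(tree, dm).rationale)

fit = models.fit_outcome(
    bundle.covariates, bundle.truth.to_numpy(dtype=object),
    bundle.outcomes, models.default_model_spec("sleep_hours"),
)
print(fit.summary_frame().set_index("term")
      .loc["pattern[early_st_volatile]"].round(3).to_string())

margins = models.adjusted_predictions(
    fit, bundle.covariates, bundle.truth.to_numpy(dtype=object), focal="pattern"
)
print(margins.table[["pattern", "estimate", "se"]].round(3).to_string(index=False))
```

prints

```
recommended by stopping rules: CH pseudo-F peaks at k=5 (2775.7); Duda-Hart ratio 0.567 (pseudo-T2 938.4) at the split to k=5
estimate    -0.213
robust_se    0.100
ci_low      -0.409
ci_high     -0.018
p_value      0.033
           pattern  estimate    se
early_st_mostly_vh     6.822 0.098
 early_st_volatile     6.728 0.074
         mostly_nw     6.554 0.164
 mostly_st_some_vh     6.805 0.051
         stable_st     6.941 0.074
```

The stopping rules recover the five generating archetypes; people on the
"early standard, then volatile" trajectory are estimated to sleep about
0.21 hours less per day than the stable standard-hours group (generating
value −0.24), and the margins table gives each pattern's covariate-adjusted
expected sleep, e.g. 6.73 vs 6.94 h/day.

## The analysis, step by step

Numbered drivers under `analysis/` run the full study on a simulated
cohort and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py      # panel + survey-style missingness
python analysis/02_build_measures.py       # derived scales, cohort filter
python analysis/03_sequence_distances.py   # TRATE costs, OM distances
python analysis/04_cluster_patterns.py     # Ward + stopping rules + plot data
python analysis/05_fit_outcome_models.py   # six robust models + Wald contrast
python analysis/06_adjusted_predictions.py # margins, pattern x social position
```

The same stages are available as one command, `worklife run-all --seed 1
--n 1000 --out run/` (see `worklife --help` for the stage-wise
subcommands); a manifest with content hashes makes reruns verifiable.

Sequence input formats: long CSV with columns `person_id, age, state`
(one row per person-year), e.g.

```
person_id,age,state
1,22,ST
1,23,ST
1,24,VH
```

or wide CSV with `person_id` and `age_22 … age_49` columns.

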