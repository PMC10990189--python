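#!/usr/bin/env python
"""Average adjusted predictions by pattern, and by pattern x social position.

For every outcome, computes delta-method average adjusted predictions at
each employment pattern from the main-effects model (the predicted-
estimates table), then refits with pattern x marker interactions (one
marker at a time: gender, race-ethnicity, education) and emits the full
prediction grid — the data behind the interaction figures.
"""

from pathlib import Path

import pandas as pd

from worklife import models

MEASURES = Path("results/measures")
CLUSTERS = Path("results/clusters")
OUT = Path("results/margins")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    covariates = pd.read_csv(MEASURES / "cohort_covariates.csv", index_col="person_id")
    outcomes = pd.read_csv(MEASURES / "cohort_outcomes.csv", index_col="person_id")
    labels = pd.read_csv(CLUSTERS / "pattern_labels.csv", index_col="person_id")[
        "pattern"
    ].to_numpy(dtype=object)

    blocks = []
    for outcome in models.DEFAULT_MODEL_SPECS:
        spec = models.default_model_spec(outcome)
        fit = models.fit_outcome(covariates, labels, outcomes, spec)
        ok = (~outcomes[outcome].isna()).to_numpy()
        res = models.adjusted_predictions(
            fit, covariates.loc[ok], labels[ok], focal=spec.pattern_col
        )
        tab = res.table.copy()
        tab.insert(0, "outcome", outcome)
        blocks.append(tab)
    main_table = pd.concat(blocks, ignore_index=True)
    main_table.to_csv(OUT / "predictions_by_pattern.csv", index=False)
    print("average adjusted predictions by pattern (main-effects models):")
    print(
        main_table.pivot(index="pattern", columns="outcome", values="estimate")
        .round(3)
        .to_string()
    )

    suite = models.interaction_suite(covariates, labels, outcomes)
    suite.to_csv(OUT / "predictions_by_pattern_and_marker.csv", index=False)
    sleep = suite[(suite["outcome"] == "sleep_hours") & (suite["marker"] == "race")]
    print("\nexample interaction margins — sleep hours by pattern x race:")
    print(
        sleep.pivot(index="pattern", columns="marker_level", values="estimate")
        .round(3)
        .to_string()
    )
    print(f"\nfull grids written to {OUT}/")


if __name__ == "__main__":
    main()
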