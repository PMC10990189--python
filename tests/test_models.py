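"""Robust regression fits, Wald contrasts, and delta-method margins."""

import numpy as np
import pandas as pd
import pytest

import worklife as wl
from worklife import models
from worklife.models import ModelSpec, Term


def simple_spec(outcome="y", family="linear", covariates=None, interaction=None):
    return ModelSpec(
        outcome=outcome,
        family=family,
        covariates=covariates or [],
        interaction=interaction,
    )


def pattern_labels(n, rng):
    levels = ["stable_st", "early_st_volatile", "mostly_nw",
              "early_st_mostly_vh", "mostly_st_some_vh"]
    return rng.choice(levels, size=n)


class TestDesign:
    def test_five_patterns_give_four_indicators(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(index=range(200))
        X, coding = models.build_design(data, pattern_labels(200, rng), simple_spec())
        pat_cols = [c for c in X.columns if c.startswith("pattern[")]
        assert len(pat_cols) == 4
        assert "pattern[stable_st]" not in X.columns

    def test_interaction_adds_product_columns(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"female": rng.integers(0, 2, 300).astype(float)})
        spec = simple_spec(
            covariates=[Term("female", kind="numeric")], interaction="female"
        )
        X, _ = models.build_design(data, pattern_labels(300, rng), spec)
        inter = [c for c in X.columns if ":" in c]
        assert len(inter) == 4  # 4 pattern dummies x 1 numeric marker

    def test_reference_rows_are_all_zero(self):
        data = pd.DataFrame({"race": ["white", "black", "white"]})
        labels = np.array(["stable_st", "mostly_nw", "stable_st"], dtype=object)
        spec = simple_spec(covariates=[Term("race", reference="white")])
        X, _ = models.build_design(data, labels, spec)
        ref_row = X.iloc[0]
        assert ref_row["const"] == 1.0
        assert (ref_row.drop("const") == 0.0).all()

    def test_missing_reference_rejected(self):
        data = pd.DataFrame({"race": ["black", "black"]})
        labels = np.array(["stable_st", "mostly_nw"], dtype=object)
        spec = simple_spec(covariates=[Term("race", reference="white")])
        with pytest.raises(ValueError, match="reference"):
            models.build_design(data, labels, spec)

    def test_frozen_coding_reused_on_counterfactual_data(self):
        data = pd.DataFrame({"race": ["white", "black", "hispanic"]})
        labels = np.array(["stable_st", "mostly_nw", "mostly_nw"], dtype=object)
        spec = simple_spec(covariates=[Term("race", reference="white")])
        X, coding = models.build_design(data, labels, spec)
        all_black = data.assign(race="black")
        X2, _ = models.build_design(all_black, labels, spec, coding=coding)
        assert list(X2.columns) == list(X.columns)
        assert (X2["race[black]"] == 1.0).all()


class TestLinearFit:
    def test_hand_solved_normal_equations(self):
        # y = 1 + 2x fitted through five points with one noise-free column
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 2.9, 5.2, 6.8, 9.0])
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = models.fit_linear_robust(y, X)
        A = np.vstack([np.ones(5), x]).T
        beta_hand = np.linalg.solve(A.T @ A, A.T @ y)
        assert np.allclose(fit.params.to_numpy(), beta_hand)

    def test_exact_fit_has_zero_robust_se(self):
        x = np.arange(10.0)
        y = 1.0 + 2.0 * x
        X = pd.DataFrame({"const": 1.0, "x": x})
        fit = models.fit_linear_robust(y, X)
        assert np.allclose(fit.params.to_numpy(), [1.0, 2.0])
        assert np.allclose(fit.se.to_numpy(), 0.0, atol=1e-8)

    def test_rank_deficiency_detected(self):
        X = pd.DataFrame({"const": 1.0, "x": np.arange(10.0), "x2": 2 * np.arange(10.0)})
        with pytest.raises(ValueError, match="rank"):
            models.fit_linear_robust(np.arange(10.0), X)

    def test_archetype_effect_recovery(self):
        """The generating sleep-hours shift is recovered from a large panel."""
        bundle = wl.generate_bundle(50_000, seed=13)
        fit = models.fit_outcome(
            bundle.covariates,
            bundle.truth.to_numpy(dtype=object),
            bundle.outcomes,
            models.default_model_spec("sleep_hours"),
        )
        assert fit.params["pattern[early_st_volatile]"] == pytest.approx(-0.24, abs=0.03)
        assert fit.family == "linear"
        assert 0 < fit.fit_stat < 1


class TestLogitFit:
    def test_null_model_flat(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"const": 1.0, "x": rng.normal(size=4000)})
        y = rng.integers(0, 2, size=4000)
        fit = models.fit_logit_robust(y, X)
        assert fit.params["const"] == pytest.approx(0.0, abs=0.1)
        assert fit.params["x"] == pytest.approx(0.0, abs=0.1)

    def test_two_by_two_log_odds_ratio(self):
        # group 1: 30/100 events; group 0: 10/100 events
        g = np.repeat([0, 1], 100)
        y = np.concatenate([np.r_[np.ones(10), np.zeros(90)],
                            np.r_[np.ones(30), np.zeros(70)]])
        X = pd.DataFrame({"const": 1.0, "g": g.astype(float)})
        fit = models.fit_logit_robust(y, X)
        lor = np.log((30 / 70) / (10 / 90))
        assert fit.params["g"] == pytest.approx(lor, abs=1e-8)

    def test_perfect_separation_reported(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        X = pd.DataFrame({"const": 1.0, "x": x})
        with pytest.raises((ValueError, RuntimeError)):
            models.fit_logit_robust(y, X)

    def test_degenerate_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(10)})
        with pytest.raises(ValueError):
            models.fit_logit_robust(np.ones(10), X)


class TestWald:
    def test_self_contrast_is_null(self):
        x = np.arange(20.0)
        fit = models.fit_linear_robust(
            3 + x + np.sin(x), pd.DataFrame({"const": 1.0, "x": x})
        )
        res = models.wald_contrast(fit, "x", "x")
        assert res.chi2 == 0.0 and res.p_value == 1.0

    def test_matches_hand_arithmetic(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {"const": 1.0, "a": rng.normal(size=500), "b": rng.normal(size=500)}
        )
        y = 1 + 0.5 * X["a"] - 0.2 * X["b"] + rng.normal(size=500)
        fit = models.fit_linear_robust(y, X)
        res = models.wald_contrast(fit, "a", "b")
        c = np.array([0.0, 1.0, -1.0])
        expected = (c @ fit.params.to_numpy()) ** 2 / (
            c @ fit.cov.to_numpy() @ c
        )
        assert res.chi2 == pytest.approx(expected, rel=1e-10)
        assert res.df == 1

    def test_chi2_equals_squared_z(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"const": 1.0, "a": rng.normal(size=300)})
        y = 2 * X["a"] + rng.normal(size=300)
        fit = models.fit_linear_robust(y, X)
        res = models.wald_contrast(fit, "a")
        z = fit.params["a"] / fit.se["a"]
        assert res.chi2 == pytest.approx(z**2, rel=1e-10)


class TestMargins:
    def _toy_fit(self, rng, family="linear", n=800):
        labels = pattern_labels(n, rng)
        data = pd.DataFrame({"female": rng.integers(0, 2, n).astype(float)})
        eta = 1.0 + 0.5 * (labels == "mostly_nw") - 0.3 * data["female"]
        if family == "linear":
            y = eta + rng.normal(size=n)
        else:
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        outcomes = pd.DataFrame({"y": y})
        spec = simple_spec(family=family, covariates=[Term("female", kind="numeric")])
        fit = models.fit_outcome(data, labels, outcomes, spec)
        return fit, data, labels

    def test_linear_two_level_example(self):
        # y = 1 + 2x exactly: margins at x=0 and x=1 are 1 and 3
        x = np.r_[np.zeros(5), np.ones(5)]
        data = pd.DataFrame({"x": x})
        labels = np.array(["stable_st", "mostly_nw"] * 5, dtype=object)
        spec = simple_spec(covariates=[Term("x", kind="numeric")])
        outcomes = pd.DataFrame({"y": 1 + 2 * x + 0.4 * (labels == "mostly_nw")})
        fit = models.fit_outcome(data, labels, outcomes, spec)
        res = models.adjusted_predictions(fit, data, labels, focal="x")
        est = res.table.set_index("x")["estimate"]
        assert est[0.0] == pytest.approx(1.0 + 0.2)  # pattern mix averaged over
        assert est[1.0] == pytest.approx(3.0 + 0.2)

    def test_linear_share_weighted_identity(self):
        rng = np.random.default_rng(5)
        fit, data, labels = self._toy_fit(rng, "linear")
        res = models.adjusted_predictions(fit, data, labels, focal="pattern")
        shares = pd.Series(labels).value_counts(normalize=True)
        weighted = sum(
            shares[row["pattern"]] * row["estimate"]
            for _, row in res.table.iterrows()
        )
        X, _ = models.build_design(data, labels, fit.spec, coding=fit.coding)
        mean_fitted = float((X.to_numpy() @ fit.params.to_numpy()).mean())
        assert weighted == pytest.approx(mean_fitted, abs=1e-8)

    def test_logit_saturated_equals_class_proportions(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 2, 500).astype(float)
        y = (rng.random(500) < np.where(g == 1, 0.7, 0.3)).astype(float)
        data = pd.DataFrame({"g": g})
        labels = np.array(["stable_st"] * 250 + ["mostly_nw"] * 250, dtype=object)
        spec = simple_spec(family="logit", covariates=[Term("g", kind="numeric")])
        outcomes = pd.DataFrame({"y": y})
        fit = models.fit_outcome(data, labels, outcomes, spec)
        res = models.adjusted_predictions(fit, data, labels, focal="g")
        est = res.table.set_index("g")["estimate"]
        # margins on the probability scale approximate observed proportions
        assert est[1.0] == pytest.approx(y[g == 1].mean(), abs=0.02)
        assert est[0.0] == pytest.approx(y[g == 0].mean(), abs=0.02)

    def test_empty_data_rejected(self):
        rng = np.random.default_rng(7)
        fit, data, labels = self._toy_fit(rng)
        with pytest.raises(ValueError):
            models.adjusted_predictions(fit, data.iloc[:0], labels[:0], focal="pattern")


class TestInteractionSuite:
    @pytest.fixture(scope="class")
    def suite(self):
        bundle = wl.generate_bundle(3000, seed=19)
        table = models.interaction_suite(
            bundle.covariates,
            bundle.truth.to_numpy(dtype=object),
            bundle.outcomes,
            outcome_names=["sleep_hours", "poor_health"],
            markers=("female", "education"),
        )
        return bundle, table

    def test_shape_contract(self, suite):
        bundle, table = suite
        # one row per pattern x marker-level combination per outcome/marker
        rows = table[(table["outcome"] == "sleep_hours") & (table["marker"] == "education")]
        assert len(rows) == 5 * bundle.covariates["education"].nunique()
        assert {"estimate", "se", "ci_low", "ci_high"} <= set(table.columns)
        assert table["se"].gt(0).all()

    def test_null_interaction_matches_main_effects(self, suite):
        """Generator has no pattern x gender effect: interaction margins stay
        within sampling error of the main-effects margins."""
        bundle, table = suite
        spec = models.default_model_spec("sleep_hours")
        labels = bundle.truth.to_numpy(dtype=object)
        fit = models.fit_outcome(bundle.covariates, labels, bundle.outcomes, spec)
        main = models.adjusted_predictions(
            fit, bundle.covariates, labels, focal="pattern"
        )
        inter = table[(table["outcome"] == "sleep_hours") & (table["marker"] == "female")]
        for _, row in main.table.iterrows():
            sub = inter[inter["pattern"] == row["pattern"]]
            # each gender-specific prediction within ~3 SE of the pooled one
            for _, irow in sub.iterrows():
                bound = 3 * np.hypot(row["se"], irow["se"]) + 0.05
                assert abs(irow["estimate"] - row["estimate"]) < bound

    def test_large_interaction_recovered_ordering(self):
        """A built-in pattern x education effect shows up in the margins."""
        from worklife import synth

        bundle = wl.generate_bundle(4000, seed=23)
        out = bundle.outcomes.copy()
        boost = (
            (bundle.truth == "early_st_volatile")
            & (bundle.covariates["education"] == "less_hs")
        ).to_numpy()
        out["sleep_hours"] = out["sleep_hours"] - 1.5 * boost
        table = models.interaction_suite(
            bundle.covariates,
            bundle.truth.to_numpy(dtype=object),
            out,
            outcome_names=["sleep_hours"],
            markers=("education",),
        )
        vol = table[table["pattern"] == "early_st_volatile"].set_index("marker_level")
        assert vol.loc["less_hs", "estimate"] == vol["estimate"].min()
        assert vol.loc["less_hs", "estimate"] < vol.loc["college", "estimate"] - 1.0
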