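"""Covariate-adjusted outcome models, Wald contrasts, and margins.

OLS (continuous outcomes) and logistic (binary outcomes) regressions of the
age-50 health measures on employment-pattern membership and the
sociodemographic covariates, with heteroskedasticity-robust (HC1)
covariance.  Post-estimation tools: single-contrast Wald chi-square tests
between pattern coefficients, and delta-method average adjusted predictions
("margins"): the sample-average model prediction with a focal variable set
to each level for everyone, with standard errors from the gradient of that
average against the robust coefficient covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

Z95 = 1.96  # reporting convention: normal 95% interval multiplier


@dataclass
class Term:
    """One right-hand-side variable: numeric, or categorical with a reference."""

    name: str
    kind: str = "categorical"  # or "numeric"
    reference: str | None = None


@dataclass
class ModelSpec:
    """Declarative model: outcome, family, pattern variable, covariates.

    The pattern variable is treatment-coded against ``pattern_ref`` (the
    stable standard-hours cluster).  ``interaction`` optionally names one
    covariate (a social-position marker) whose dummies are crossed with the
    pattern dummies — one marker at a time.
    """

    outcome: str
    family: str  # "linear" | "logit"
    pattern_col: str = "pattern"
    pattern_ref: str = "stable_st"
    covariates: list[Term] = field(default_factory=list)
    interaction: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logit"):
            raise ValueError("family must be 'linear' or 'logit'")
        if self.interaction is not None:
            names = [t.name for t in self.covariates]
            if self.interaction not in names:
                raise ValueError(
                    f"interaction marker {self.interaction!r} not among covariates"
                )


def default_covariate_terms() -> list[Term]:
    """Covariate terms matching the default synthetic covariate table."""
    return [
        Term("female", kind="numeric"),
        Term("race", reference="white"),
        Term("education", reference="hs"),
        Term("age1979", kind="numeric"),
        Term("n_marriages", kind="numeric"),
        Term("n_children", kind="numeric"),
        Term("years_welfare", kind="numeric"),
        Term("years_poverty", kind="numeric"),
        Term("weekly_hours", reference="mostly_full_time"),
        Term("occupation", reference="mostly_service"),
    ]


DEFAULT_MODEL_SPECS = {
    "sleep_hours": "linear",
    "sleep_quality": "linear",
    "poor_health": "logit",
    "sf12_physical": "linear",
    "sf12_mental": "linear",
    "cesd_risk": "logit",
}


def default_model_spec(outcome: str, interaction: str | None = None) -> ModelSpec:
    if outcome not in DEFAULT_MODEL_SPECS:
        raise KeyError(f"no default model for outcome {outcome!r}")
    return ModelSpec(
        outcome=outcome,
        family=DEFAULT_MODEL_SPECS[outcome],
        covariates=default_covariate_terms(),
        interaction=interaction,
    )


# ---------------------------------------------------------------------------
# design construction
#
# The coding is derived once from the estimation data (validating reference
# levels) and then frozen: margins re-evaluate the same columns on modified
# data, so counterfactually setting every row to one level cannot change the
# design's column set.
# ---------------------------------------------------------------------------


def _levels_minus_ref(series: pd.Series, reference, varname: str) -> list:
    levels = pd.unique(series.dropna())
    if reference not in set(levels):
        raise ValueError(f"reference level {reference!r} absent from {varname!r}")
    others = [lv for lv in levels if lv != reference]
    others.sort(key=str)
    return others


def derive_coding(df: pd.DataFrame, spec: ModelSpec) -> dict:
    """Ordered map: design column -> column recipe tuple.

    Recipes: ``("const",)``, ``("num", var)``, ``("cat", var, level)``,
    ``("int", pattern_level, marker_var, marker_level_or_None)``.
    """
    coding: dict[str, tuple] = {"const": ("const",)}
    pat_levels = _levels_minus_ref(
        df[spec.pattern_col], spec.pattern_ref, spec.pattern_col
    )
    for lv in pat_levels:
        coding[f"{spec.pattern_col}[{lv}]"] = ("cat", spec.pattern_col, lv)
    for term in spec.covariates:
        if term.name not in df.columns:
            raise KeyError(f"covariate {term.name!r} not in data")
        if term.kind == "numeric":
            coding[term.name] = ("num", term.name)
        else:
            for lv in _levels_minus_ref(df[term.name], term.reference, term.name):
                coding[f"{term.name}[{lv}]"] = ("cat", term.name, lv)
    if spec.interaction is not None:
        marker = spec.interaction
        term = next(t for t in spec.covariates if t.name == marker)
        if term.kind == "numeric":
            for plv in pat_levels:
                coding[f"{spec.pattern_col}[{plv}]:{marker}"] = (
                    "int", plv, marker, None,
                )
        else:
            for plv in pat_levels:
                for mlv in _levels_minus_ref(df[marker], term.reference, marker):
                    coding[f"{spec.pattern_col}[{plv}]:{marker}[{mlv}]"] = (
                        "int", plv, marker, mlv,
                    )
    return coding


def _evaluate_design(df: pd.DataFrame, spec: ModelSpec, coding: dict) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for col, recipe in coding.items():
        if recipe[0] == "const":
            X[col] = 1.0
        elif recipe[0] == "num":
            X[col] = df[recipe[1]].astype(float)
        elif recipe[0] == "cat":
            X[col] = (df[recipe[1]] == recipe[2]).astype(float)
        elif recipe[0] == "int":
            _, plv, marker, mlv = recipe
            left = (df[spec.pattern_col] == plv).astype(float)
            right = (
                df[marker].astype(float) if mlv is None
                else (df[marker] == mlv).astype(float)
            )
            X[col] = left * right
        else:  # pragma: no cover
            raise ValueError(f"unknown recipe {recipe!r}")
    return X


def build_design(
    data: pd.DataFrame, labels, spec: ModelSpec, coding: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Treatment-coded design matrix with intercept, plus the coding map.

    Pass a previously derived ``coding`` to evaluate the same columns on
    new or counterfactually modified data.
    """
    df = data.copy()
    df[spec.pattern_col] = np.asarray(labels, dtype=object)
    if coding is None:
        coding = derive_coding(df, spec)
    return _evaluate_design(df, spec, coding), coding


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class ModelFit:
    """Coefficients with robust covariance and reporting-scale intervals."""

    params: pd.Series
    cov: pd.DataFrame
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    n: int
    fit_stat: float  # R^2 (linear) or McFadden pseudo-R^2 (logit)
    family: str
    spec: ModelSpec | None = None
    coding: dict | None = None

    def summary_frame(self) -> pd.DataFrame:
        se = self.se.replace(0.0, np.nan)
        z = self.params / se
        p = 2 * stats.norm.sf(np.abs(z))
        out = pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "robust_se": self.se.to_numpy(),
                "ci_low": self.ci_low.to_numpy(),
                "ci_high": self.ci_high.to_numpy(),
                "p_value": p,
            }
        )
        if self.family == "logit":
            out["odds_ratio"] = np.exp(out["estimate"])
        return out


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design: rank {rank} < {X.shape[1]} columns "
            "(collinear or empty categories)"
        )


def _wrap(res, X: pd.DataFrame, family: str, fit_stat: float, spec, coding) -> ModelFit:
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    se = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    return ModelFit(
        params=params,
        cov=cov,
        se=se,
        ci_low=params - Z95 * se,
        ci_high=params + Z95 * se,
        n=int(X.shape[0]),
        fit_stat=float(fit_stat),
        family=family,
        spec=spec,
        coding=coding,
    )


def fit_linear_robust(
    y, X: pd.DataFrame, spec: ModelSpec | None = None, coding: dict | None = None
) -> ModelFit:
    """OLS with HC1 heteroskedasticity-robust covariance."""
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than design columns")
    _check_design(X)
    res = sm.OLS(y, X.to_numpy()).fit(cov_type="HC1")
    return _wrap(res, X, "linear", res.rsquared, spec, coding)


def fit_logit_robust(
    y01,
    X: pd.DataFrame,
    spec: ModelSpec | None = None,
    coding: dict | None = None,
    maxiter: int = 100,
) -> ModelFit:
    """Maximum-likelihood logit with HC1 sandwich covariance.

    Convergence: relative log-likelihood change below 1e-10, at most
    ``maxiter`` Newton iterations; perfect separation is reported as an
    error rather than returning divergent coefficients.
    """
    y = np.asarray(y01, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all() or len(classes) < 2:
        raise ValueError("outcome must be binary with both classes present")
    _check_design(X)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    model = sm.Logit(y, X.to_numpy())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = model.fit(disp=0, maxiter=maxiter, tol=1e-10, cov_type="HC1")
    except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError) as err:
        raise ValueError(f"logit fit failed (possible separation): {err}") from None
    if not res.mle_retvals.get("converged", True):
        # drifting coefficients with a vanishing score indicate
        # quasi-separation in a sparse category rather than a bad optimizer
        drifting = [
            X.columns[j] for j, b in enumerate(np.atleast_1d(res.params))
            if abs(b) > 15
        ]
        if drifting:
            raise ValueError(
                f"logit fit failed (possible separation): coefficients "
                f"drifting for {drifting}"
            )
        raise RuntimeError("logit fit failed to converge")
    return _wrap(res, X, "logit", res.prsquared, spec, coding)


def fit_outcome(
    data: pd.DataFrame, labels, outcomes: pd.DataFrame, spec: ModelSpec
) -> ModelFit:
    """Build the design from a spec and fit the appropriate family.

    Interaction cells absent from the data yield all-zero design columns;
    these are dropped with a warning (the combination then carries no
    interaction adjustment) so sparse cross-classifications remain fittable.
    """
    y = outcomes[spec.outcome]
    ok = ~y.isna()
    labels = np.asarray(labels, dtype=object)
    X, coding = build_design(data.loc[ok], labels[ok.to_numpy()], spec)
    empty = [c for c in X.columns if c != "const" and (X[c] == 0).all()]
    if empty:
        warnings.warn(
            f"dropping empty design cells: {empty}", stacklevel=2
        )
        X = X.drop(columns=empty)
        coding = {c: r for c, r in coding.items() if c not in empty}
    y = y.loc[ok]
    if spec.family == "linear":
        return fit_linear_robust(y, X, spec, coding)
    try:
        return fit_logit_robust(y, X, spec, coding)
    except ValueError as err:
        # a sparse interaction cell with no (or all) events separates the
        # likelihood; such cells carry no estimable interaction term and
        # are dropped, mirroring the empty-cell rule above
        drifting = [
            c for c in X.columns if ":" in c and f"'{c}'" in str(err)
        ]
        if not drifting:
            raise
        warnings.warn(
            f"dropping quasi-separated interaction cells: {drifting}",
            stacklevel=2,
        )
        X = X.drop(columns=drifting)
        coding = {c: r for c, r in coding.items() if c not in drifting}
        return fit_logit_robust(y, X, spec, coding)


# ---------------------------------------------------------------------------
# Wald contrasts
# ---------------------------------------------------------------------------


@dataclass
class WaldResult:
    contrast: str
    chi2: float
    df: int
    p_value: float


def wald_contrast(fit: ModelFit, term_a, term_b: str | None = None) -> WaldResult:
    """Wald chi-square for one linear contrast of coefficients.

    ``term_a`` may be a coefficient name (contrasted against ``term_b``,
    i.e. ``b_a - b_b = 0``) or a full contrast vector aligned to the
    coefficient order.  ``chi2 = (c'b)^2 / (c'Vc)`` on 1 degree of freedom,
    using the robust covariance.
    """
    idx = list(fit.params.index)
    if isinstance(term_a, str):
        if term_a not in idx:
            raise KeyError(f"unknown coefficient {term_a!r}")
        c = np.zeros(len(idx))
        c[idx.index(term_a)] = 1.0
        desc = term_a
        if term_b is not None:
            if term_b not in idx:
                raise KeyError(f"unknown coefficient {term_b!r}")
            c[idx.index(term_b)] -= 1.0
            desc = f"{term_a} - {term_b}"
    else:
        c = np.asarray(term_a, dtype=float)
        if c.shape != (len(idx),):
            raise ValueError("contrast vector length does not match coefficients")
        desc = "custom contrast"
    est = float(c @ fit.params.to_numpy())
    var = float(c @ fit.cov.to_numpy() @ c)
    if var <= 0:
        if est == 0.0:
            return WaldResult(contrast=desc, chi2=0.0, df=1, p_value=1.0)
        raise ValueError("zero-variance contrast")
    chi2 = est**2 / var
    return WaldResult(
        contrast=desc, chi2=chi2, df=1, p_value=float(stats.chi2.sf(chi2, 1))
    )


# ---------------------------------------------------------------------------
# average adjusted predictions (margins)
# ---------------------------------------------------------------------------


@dataclass
class MarginsResult:
    """Tidy table of average adjusted predictions with delta-method CIs."""

    table: pd.DataFrame
    focal: tuple[str, ...]


def adjusted_predictions(
    fit: ModelFit,
    data: pd.DataFrame,
    labels,
    focal,
    levels: dict | None = None,
) -> MarginsResult:
    """Average adjusted predictions over the estimation sample.

    For each combination of the ``focal`` variables' levels, every row's
    focal values are set to that combination, the model prediction is
    averaged over all rows (probability scale for logit), and the
    delta-method standard error is ``sqrt(g' V g)`` with ``g`` the gradient
    of the averaged prediction with respect to the coefficients.
    """
    if fit.spec is None or fit.coding is None:
        raise ValueError("fit carries no ModelSpec/coding; refit via fit_outcome")
    if len(data) == 0:
        raise ValueError("empty data")
    spec = fit.spec
    focal = (focal,) if isinstance(focal, str) else tuple(focal)
    df = data.copy()
    df[spec.pattern_col] = np.asarray(labels, dtype=object)
    levels = levels or {}
    level_sets = []
    for var in focal:
        if var in levels:
            level_sets.append(list(levels[var]))
        else:
            level_sets.append(sorted(df[var].dropna().unique(), key=str))

    beta = fit.params.to_numpy()
    V = fit.cov.to_numpy()
    rows = []
    for combo in product(*level_sets):
        mod = df.copy()
        for var, lv in zip(focal, combo):
            mod[var] = lv
        X = _evaluate_design(mod, spec, fit.coding).to_numpy()
        eta = X @ beta
        if fit.family == "linear":
            pred = float(eta.mean())
            grad = X.mean(axis=0)
        else:
            p = expit(eta)
            pred = float(p.mean())
            grad = ((p * (1 - p))[:, None] * X).mean(axis=0)
        se = float(np.sqrt(grad @ V @ grad))
        observed = np.ones(len(df), dtype=bool)
        for var, lv in zip(focal, combo):
            observed &= (df[var] == lv).to_numpy()
        row = dict(zip(focal, combo))
        row.update(
            {
                "estimate": pred,
                "se": se,
                "ci_low": pred - Z95 * se,
                "ci_high": pred + Z95 * se,
                "n_cell": int(observed.sum()),
            }
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    if (table["n_cell"] == 0).any():
        warnings.warn(
            f"{int((table['n_cell'] == 0).sum())} focal combinations are "
            "absent from the data",
            stacklevel=2,
        )
    return MarginsResult(table=table, focal=focal)


def interaction_suite(
    data: pd.DataFrame,
    labels,
    outcomes: pd.DataFrame,
    outcome_names=None,
    markers=("female", "race", "education"),
) -> pd.DataFrame:
    """Pattern-by-marker interaction models with margins, stacked tidily.

    For each outcome and each social-position marker (one at a time, as in
    the source design), fits the interaction model and computes average
    adjusted predictions for every pattern x marker-level combination.
    Returns one long table keyed by outcome, marker, pattern and level.
    """
    if outcome_names is None:
        outcome_names = list(DEFAULT_MODEL_SPECS)
    labels = np.asarray(labels, dtype=object)
    blocks = []
    for outcome in outcome_names:
        for marker in markers:
            spec = default_model_spec(outcome, interaction=marker)
            fit = fit_outcome(data, labels, outcomes, spec)
            ok = (~outcomes[outcome].isna()).to_numpy()
            margins = adjusted_predictions(
                fit, data.loc[ok], labels[ok], focal=(spec.pattern_col, marker)
            )
            tab = margins.table.copy()
            tab.insert(0, "outcome", outcome)
            tab.insert(1, "marker", marker)
            tab = tab.rename(columns={marker: "marker_level"})
            blocks.append(tab)
    return pd.concat(blocks, ignore_index=True)
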