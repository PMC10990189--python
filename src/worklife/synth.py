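"""Seeded generator of NLSY-style panels: sequences, covariates, outcomes.

The study design this package analyzes — yearly work-schedule states from
ages 22 to 49 linked to health at age 50 — relies on restricted-access
survey data.  This module generates panels with the same statistical
structure so the whole pipeline is testable end to end: five latent
trajectory archetypes with realistic population shares, sticky Markov state
emission within archetype, covariates drawn from archetype-conditional
distributions, and outcomes generated from linear/logistic models with
archetype effects on the scale reported for this cohort.

All randomness flows through one integer seed; each operation derives its
own independent sub-stream deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import measures
from .sequences import MISSING, N_AGES, STATES, SequencePanel

# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------


@dataclass
class ArchetypeSpec:
    """One latent trajectory archetype.

    ``profile`` is a ``(28, 5)`` matrix of per-age emission probabilities
    over the state alphabet; ``stickiness`` is the probability of repeating
    the previous year's state instead of a fresh draw (yearly employment
    states are strongly autocorrelated); ``share`` is the population
    proportion of the archetype.
    """

    name: str
    share: float
    profile: np.ndarray
    stickiness: float = 0.8

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if self.profile.shape != (N_AGES, len(STATES)):
            raise ValueError(
                f"profile must be ({N_AGES}, {len(STATES)}); got {self.profile.shape}"
            )
        if not np.allclose(self.profile.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each per-age probability vector must sum to 1")
        if (self.profile < 0).any():
            raise ValueError("profile probabilities must be nonnegative")
        if not 0 <= self.share <= 1:
            raise ValueError("share must lie in [0, 1]")
        if not 0 <= self.stickiness <= 1:
            raise ValueError("stickiness must lie in [0, 1]")


def _flat_profile(weights: dict[str, float]) -> np.ndarray:
    row = np.array([weights.get(s, 0.0) for s in STATES], dtype=float)
    row = row / row.sum()
    return np.tile(row, (N_AGES, 1))


def _piecewise_profile(
    early: dict[str, float], late: dict[str, float], switch_age: int = 30
) -> np.ndarray:
    prof = _flat_profile(early)
    prof[switch_age - 22 :] = _flat_profile(late)[switch_age - 22 :]
    return prof


#: population shares of the five archetypes (cohort proportions)
DEFAULT_SHARES = {
    "mostly_nw": 0.1074,
    "early_st_mostly_vh": 0.1152,
    "early_st_volatile": 0.1711,
    "mostly_st_some_vh": 0.3480,
    "stable_st": 0.2583,
}


#: per-archetype probability of repeating last year's state.  Groups defined
#: by schedule *stability* persist strongly; the volatile and variable-hours
#: mixing groups change schedules often (that churn is what defines them),
#: which also concentrates their realized state-composition around the
#: profile and keeps the archetypes well separated.
DEFAULT_STICKINESS = {
    "mostly_nw": 0.70,
    "early_st_mostly_vh": 0.45,
    "early_st_volatile": 0.25,
    "mostly_st_some_vh": 0.15,
    "stable_st": 0.55,
}


def default_archetypes(stickiness: float | dict | None = None) -> list[ArchetypeSpec]:
    """The five work-schedule trajectory archetypes with default profiles.

    The profiles are deliberately well separated: a mostly-not-working
    group; two groups that work standard hours through their 20s and then
    switch at 30 (one into predominantly variable hours, one into a volatile
    evening/night/variable mix); a standard-hours group with a steady
    admixture of variable hours; and a stable standard-hours group.
    ``stickiness`` may override the per-archetype defaults with a scalar or
    a name-keyed mapping.
    """
    profiles = {
        "mostly_nw": _flat_profile(
            {"NW": 0.92, "ST": 0.05, "EV": 0.01, "NI": 0.01, "VH": 0.01}
        ),
        "early_st_mostly_vh": _piecewise_profile(
            {"ST": 0.94, "NW": 0.02, "EV": 0.01, "NI": 0.01, "VH": 0.02},
            {"VH": 0.94, "ST": 0.02, "NW": 0.02, "EV": 0.01, "NI": 0.01},
        ),
        "early_st_volatile": _piecewise_profile(
            {"ST": 0.94, "NW": 0.02, "EV": 0.02, "NI": 0.01, "VH": 0.01},
            {"ST": 0.03, "EV": 0.35, "NI": 0.35, "VH": 0.25, "NW": 0.02},
        ),
        "mostly_st_some_vh": _flat_profile(
            {"ST": 0.64, "VH": 0.34, "NW": 0.01, "EV": 0.005, "NI": 0.005}
        ),
        "stable_st": _flat_profile(
            {"ST": 0.98, "NW": 0.008, "EV": 0.002, "NI": 0.002, "VH": 0.008}
        ),
    }
    if stickiness is None:
        stick = dict(DEFAULT_STICKINESS)
    elif isinstance(stickiness, dict):
        stick = {**DEFAULT_STICKINESS, **stickiness}
    else:
        stick = {k: float(stickiness) for k in profiles}
    return [
        ArchetypeSpec(name=k, share=DEFAULT_SHARES[k], profile=v, stickiness=stick[k])
        for k, v in profiles.items()
    ]


ARCHETYPE_NAMES = tuple(DEFAULT_SHARES)
REFERENCE_ARCHETYPE = "stable_st"


# ---------------------------------------------------------------------------
# bundle container
# ---------------------------------------------------------------------------


@dataclass
class SyntheticPanelBundle:
    """Sequences + covariates + outcomes sharing one set of person ids."""

    sequences: SequencePanel
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    truth: pd.Series | None
    seed: int | None = None

    def __post_init__(self) -> None:
        ids = self.sequences.ids
        if not np.array_equal(self.covariates.index.to_numpy(), ids):
            raise ValueError("covariate ids do not match sequence ids")
        if not np.array_equal(self.outcomes.index.to_numpy(), ids):
            raise ValueError("outcome ids do not match sequence ids")
        if self.truth is not None and not np.array_equal(
            self.truth.index.to_numpy(), ids
        ):
            raise ValueError("truth ids do not match sequence ids")

    @property
    def n(self) -> int:
        return self.sequences.n


def _stream(seed: int, stage: int) -> np.random.Generator:
    """Deterministic per-stage sub-stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stage)]))


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def generate_sequences(
    archetypes: list[ArchetypeSpec], n: int, seed: int
) -> tuple[SequencePanel, pd.Series]:
    """Draw ``n`` sticky-Markov state sequences from the archetype mixture.

    Person ``i`` first draws an archetype from the configured shares, then
    states age by age from its per-age profile; with probability
    ``stickiness`` the previous state is copied instead of a fresh draw.
    Returns the panel and the latent archetype labels (the generation truth).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    shares = np.array([a.share for a in archetypes])
    if not np.isclose(shares.sum(), 1.0, atol=1e-9):
        raise ValueError("archetype shares must sum to 1")
    rng = _stream(seed, 1)
    arch_idx = rng.choice(len(archetypes), size=n, p=shares)
    codes = np.empty((n, N_AGES), dtype=np.int16)
    # cumulative profiles per archetype for vectorized inverse-CDF sampling
    cums = [np.cumsum(a.profile, axis=1) for a in archetypes]
    stick = np.array([a.stickiness for a in archetypes])
    for t in range(N_AGES):
        u = rng.random(n)
        fresh = np.empty(n, dtype=np.int16)
        for k in range(len(archetypes)):
            sel = arch_idx == k
            if sel.any():
                fresh[sel] = np.searchsorted(cums[k][t], u[sel], side="right")
        fresh = np.minimum(fresh, len(STATES) - 1)
        if t == 0:
            codes[:, 0] = fresh
        else:
            repeat = rng.random(n) < stick[arch_idx]
            codes[:, t] = np.where(repeat, codes[:, t - 1], fresh)
    ids = np.arange(n)
    labels = pd.Series(
        np.array([archetypes[k].name for k in arch_idx], dtype=object),
        index=ids,
        name="archetype",
    )
    return SequencePanel(ids=ids, codes=codes), labels


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


@dataclass
class CovariateConfig:
    """Archetype-conditional covariate distributions.

    ``categorical`` maps a column name to ``(levels, probs)`` where ``probs``
    is an ``{archetype: probability vector}`` mapping; ``poisson`` maps a
    column to per-archetype means (counts, clipped to ``count_max``);
    ``age`` gives the (mean, sd) of the baseline-age draw per archetype.
    """

    categorical: dict = field(default_factory=dict)
    poisson: dict = field(default_factory=dict)
    age: dict = field(default_factory=dict)
    count_max: int = 28

    def validate(self, archetype_names) -> None:
        for col, (levels, probs) in self.categorical.items():
            for name in archetype_names:
                p = np.asarray(probs[name], dtype=float)
                if len(p) != len(levels):
                    raise ValueError(f"{col}: probability/level length mismatch")
                if ((p < 0) | (p > 1)).any():
                    raise ValueError(f"{col}: probabilities outside [0, 1]")
                if not np.isclose(p.sum(), 1.0, atol=1e-6):
                    raise ValueError(f"{col}: probabilities must sum to 1")


def default_covariate_config() -> CovariateConfig:
    """Default archetype-conditional distributions.

    Category probabilities follow the cohort's published cross-tabulations
    by employment pattern (gender, race-ethnicity, education, weekly-hours
    and occupation categories); count covariates use the published
    per-pattern means.  Only marginal/cross-tab structure is modelled.
    """
    a = ARCHETYPE_NAMES

    def tab(*cols):
        # columns given in archetype order
        return {name: np.asarray(col, dtype=float) / 100.0 for name, col in zip(a, cols)}

    categorical = {
        "female": (
            ["0", "1"],
            tab(*[[100 - f, f] for f in (72.72, 45.92, 44.54, 55.62, 46.86)]),
        ),
        "race": (
            ["white", "black", "hispanic", "other"],
            tab(
                [38.83, 39.21, 21.70, 0.26],
                [57.16, 27.81, 14.32, 0.71],
                [41.99, 38.01, 18.80, 1.20],
                [48.92, 28.63, 21.35, 1.10],
                [57.94, 21.90, 18.68, 1.48],
            ),
        ),
        "education": (
            ["less_hs", "hs", "some_college", "college"],
            tab(
                [36.80, 39.09, 16.88, 7.23],
                [14.56, 42.60, 27.69, 15.15],
                [20.00, 49.48, 22.47, 8.05],
                [20.56, 42.34, 24.05, 13.05],
                [13.46, 41.06, 23.85, 21.63],
            ),
        ),
        "weekly_hours": (
            ["mostly_full_time", "mostly_part_time", "mixed"],
            tab(
                [13.07, 82.87, 4.06],
                [79.53, 18.70, 1.77],
                [82.87, 14.18, 2.95],
                [77.63, 19.51, 2.86],
                [95.04, 4.38, 0.58],
            ),
        ),
        "occupation": (
            [
                "mostly_professional_managerial",
                "mostly_sales",
                "mostly_service",
                "mostly_other",
                "mixed",
            ],
            tab(
                [11.55, 3.55, 51.78, 21.44, 11.68],
                [28.88, 2.01, 34.20, 27.34, 7.57],
                [16.41, 1.59, 41.91, 34.27, 5.82],
                [22.37, 2.78, 37.56, 31.41, 5.88],
                [36.04, 2.85, 26.87, 31.13, 3.11],
            ),
        ),
    }
    poisson = {
        "n_marriages": dict(zip(a, (1.11, 1.36, 1.17, 1.33, 1.24))),
        "n_children": dict(zip(a, (2.43, 1.85, 1.84, 1.98, 1.88))),
        "years_welfare": dict(zip(a, (6.67, 1.82, 2.00, 2.41, 0.92))),
        "years_poverty": dict(zip(a, (6.96, 2.07, 2.49, 2.96, 1.34))),
    }
    age = {name: (m, 2.23) for name, m in zip(a, (17.67, 17.49, 17.47, 17.52, 17.70))}
    return CovariateConfig(categorical=categorical, poisson=poisson, age=age)


def generate_covariates(
    labels: pd.Series, config: CovariateConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw covariates from archetype-conditional distributions."""
    if config is None:
        config = default_covariate_config()
    names = sorted(set(labels))
    config.validate(names)
    rng = _stream(seed, 2)
    n = len(labels)
    lab = labels.to_numpy()
    out: dict[str, np.ndarray] = {}

    for col, (levels, probs) in config.categorical.items():
        vals = np.empty(n, dtype=object)
        for name in names:
            sel = lab == name
            if sel.any():
                vals[sel] = rng.choice(levels, size=int(sel.sum()), p=probs[name])
        out[col] = vals
    for col, means in config.poisson.items():
        mu = np.array([means[x] for x in lab])
        out[col] = np.minimum(rng.poisson(mu), config.count_max).astype(float)
    if config.age:
        mean = np.array([config.age[x][0] for x in lab])
        sd = np.array([config.age[x][1] for x in lab])
        out["age1979"] = np.clip(np.round(rng.normal(mean, sd)), 14, 22)

    frame = pd.DataFrame(out, index=labels.index)
    if "female" in frame:
        frame["female"] = frame["female"].astype(float)
    return frame


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

CONTINUOUS_OUTCOMES = ("sleep_hours", "sleep_quality", "sf12_physical", "sf12_mental")
BINARY_OUTCOMES = ("poor_health", "cesd_risk")

#: factor loading of the four sleep-quality items on the latent quality
#: score, set so the 4-level Likert items yield Cronbach's alpha near the
#: instrument's published reliability of 0.84
QUALITY_LOADING: float = 0.80

#: half the weekday/weekend split applied around the latent weekly mean
#: (matches the observed weekday-vs-weekend gap of about 0.6 h)
SLEEP_SPLIT: float = 0.295


@dataclass
class EffectSpec:
    """Generating model for one outcome.

    ``archetype_effects`` are additive (continuous family) or log-odds
    (binary family) shifts relative to the stable standard-hours reference,
    whose own effect must be 0.  ``covariate_effects`` maps a numeric column
    to a slope, or a categorical column to a ``{level: shift}`` dict.
    """

    outcome: str
    family: str
    intercept: float
    archetype_effects: dict
    covariate_effects: dict = field(default_factory=dict)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logit"):
            raise ValueError("family must be 'linear' or 'logit'")
        if self.family == "linear" and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive for continuous outcomes")
        ref = self.archetype_effects.get(REFERENCE_ARCHETYPE, 0.0)
        if ref != 0.0:
            raise ValueError("reference archetype effect must be 0")


def default_effects() -> list[EffectSpec]:
    """Generating effects on the scale of the published regression tables."""
    def arch(nw, evh, vol, svh):
        return {
            "mostly_nw": nw,
            "early_st_mostly_vh": evh,
            "early_st_volatile": vol,
            "mostly_st_some_vh": svh,
            "stable_st": 0.0,
        }

    race = lambda b, h, o: {"black": b, "hispanic": h, "other": o, "white": 0.0}
    edu = lambda lo, sc, co: {
        "less_hs": lo,
        "some_college": sc,
        "college": co,
        "hs": 0.0,
    }
    return [
        EffectSpec(
            "sleep_hours",
            "linear",
            intercept=7.05,
            archetype_effects=arch(-0.14, -0.23, -0.24, -0.10),
            covariate_effects={
                "female": 0.09,
                "race": race(-0.15, 0.03, 0.01),
                "education": edu(-0.04, 0.00, 0.07),
                "n_marriages": -0.04,
                "n_children": -0.02,
                "years_welfare": -0.01,
            },
            noise_sd=1.35,
        ),
        EffectSpec(
            "sleep_quality",
            "linear",
            intercept=0.15,
            archetype_effects=arch(-0.07, -0.05, -0.08, -0.05),
            covariate_effects={
                "female": -0.14,
                "race": race(0.12, 0.10, 0.10),
                "education": edu(-0.12, 0.00, 0.08),
                "years_welfare": -0.02,
            },
            noise_sd=0.80,
        ),
        EffectSpec(
            "poor_health",
            "logit",
            intercept=-2.05,
            archetype_effects=arch(0.27, 0.08, 0.45, 0.18),
            covariate_effects={
                "female": -0.02,
                "race": race(0.08, 0.03, 0.08),
                "education": edu(0.36, -0.17, -0.81),
                "years_welfare": 0.08,
                "years_poverty": 0.04,
            },
        ),
        EffectSpec(
            "sf12_physical",
            "linear",
            intercept=51.4,
            archetype_effects=arch(-1.97, -0.89, -1.42, -0.62),
            covariate_effects={
                "female": -0.52,
                "race": race(0.64, 0.52, 1.08),
                "education": edu(-1.20, 0.18, 1.68),
            },
            noise_sd=9.0,
        ),
        EffectSpec(
            "sf12_mental",
            "linear",
            intercept=54.0,
            archetype_effects=arch(-0.65, -0.20, -0.82, -0.25),
            covariate_effects={
                "female": -1.24,
                "race": race(1.40, 1.05, 0.22),
                "education": edu(-0.77, 0.03, 0.13),
            },
            noise_sd=8.5,
        ),
        EffectSpec(
            "cesd_risk",
            "logit",
            intercept=-2.10,
            archetype_effects=arch(0.26, 0.22, 0.36, 0.22),
            covariate_effects={
                "female": 0.30,
                "race": race(-0.42, -0.31, -0.35),
                "education": edu(0.26, -0.13, -0.57),
                "years_welfare": 0.05,
            },
        ),
    ]


def _linear_predictor(
    spec: EffectSpec, labels: np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    eta = np.full(len(labels), float(spec.intercept))
    missing_arch = set(labels) - set(spec.archetype_effects)
    if missing_arch:
        raise ValueError(f"no archetype effect declared for {sorted(missing_arch)}")
    eta += np.array([spec.archetype_effects[x] for x in labels])
    for col, eff in spec.covariate_effects.items():
        if col not in covariates.columns:
            raise KeyError(f"effect references unknown covariate {col!r}")
        values = covariates[col]
        if isinstance(eff, dict):
            eta += values.map(lambda v: eff.get(v, 0.0)).to_numpy(dtype=float)
        else:
            eta += float(eff) * values.to_numpy(dtype=float)
    return eta


def cesd_items_from_total(total: int, rng: np.random.Generator) -> np.ndarray:
    """Distribute a 0-21 total over seven 0-3 items.

    Each item gets the even split ``total // 7``; the remainder is assigned
    one point each to a random subset of items.  A total of 21 therefore
    gives all items 3, and the item sum always equals the total.
    """
    total = int(total)
    if not 0 <= total <= 21:
        raise ValueError("CES-D total must lie in [0, 21]")
    base, rem = divmod(total, 7)
    items = np.full(7, base, dtype=float)
    if rem:
        items[rng.choice(7, size=rem, replace=False)] += 1
    return items


def quality_items_from_latent(
    z: np.ndarray, rng: np.random.Generator, loading: float = QUALITY_LOADING
) -> np.ndarray:
    """Four 1-4 Likert sleep-problem items from a latent quality score.

    One-factor model: each item's continuous score loads ``loading`` on the
    standardized latent quality, with independent Gaussian uniqueness, then
    is cut at equal-probability thresholds into four ordered categories.
    Items are coded as problem frequency (4 = worst), i.e. reversed relative
    to the latent quality, matching the raw survey orientation.
    """
    z = np.asarray(z, dtype=float)
    zs = (z - z.mean()) / z.std(ddof=0)
    uniq = np.sqrt(1.0 - loading**2)
    from scipy.stats import norm

    cuts = norm.ppf([0.25, 0.5, 0.75])
    items = np.empty((len(z), 4))
    for j in range(4):
        latent = loading * zs + uniq * rng.standard_normal(len(z))
        cat = np.searchsorted(cuts, latent) + 1  # 1..4, higher = better
        items[:, j] = 5 - cat  # reverse: higher = more trouble
    return items


def generate_outcomes(
    labels: pd.Series,
    covariates: pd.DataFrame,
    effects: list[EffectSpec] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Item-level and derived outcome columns from the generating models.

    Continuous outcomes are intercept + archetype effect + covariate effects
    + Gaussian noise; binary outcomes are Bernoulli draws on the
    inverse-logit of the linear predictor.  Item-level survey columns
    (weekday/weekend sleep hours, four sleep-quality Likert items, the
    1-5 general-health rating, seven CES-D items) are emitted alongside, and
    the derived scales are recomputed from those items with the measures
    module so that derivation round-trips exactly up to discretization.
    """
    if effects is None:
        effects = default_effects()
    known = CONTINUOUS_OUTCOMES + BINARY_OUTCOMES
    rng = _stream(seed, 3)
    lab = labels.to_numpy()
    n = len(lab)
    out = pd.DataFrame(index=labels.index)

    by_name = {}
    for spec in effects:
        if spec.outcome not in known:
            raise ValueError(f"unknown outcome {spec.outcome!r}")
        by_name[spec.outcome] = spec

    for name, spec in by_name.items():
        eta = _linear_predictor(spec, lab, covariates)
        if spec.family == "linear":
            out[name + "_latent"] = eta + spec.noise_sd * rng.standard_normal(n)
        else:
            out[name + "_latent"] = (rng.random(n) < expit(eta)).astype(float)

    # --- item-level emission + derived scales ---
    if "sleep_hours_latent" in out:
        latent = out["sleep_hours_latent"].to_numpy()
        out["sleep_weekday"] = np.clip(latent - SLEEP_SPLIT, 0, 24)
        out["sleep_weekend"] = np.clip(latent + SLEEP_SPLIT, 0, 24)
        out["sleep_hours"] = measures.weekly_sleep_average(
            out["sleep_weekday"], out["sleep_weekend"]
        )
    if "sleep_quality_latent" in out:
        items = quality_items_from_latent(
            out["sleep_quality_latent"].to_numpy(), rng
        )
        for j in range(4):
            out[f"sleep_quality_item{j + 1}"] = items[:, j]
        score, _alpha = measures.sleep_quality_score(
            out[[f"sleep_quality_item{j + 1}" for j in range(4)]]
        )
        out["sleep_quality"] = score
    if "poor_health_latent" in out:
        poor = out["poor_health_latent"].to_numpy()
        rating = np.where(
            poor == 1,
            rng.choice([4, 5], size=n, p=[0.7, 0.3]),
            rng.choice([1, 2, 3], size=n, p=[0.25, 0.45, 0.30]),
        ).astype(float)
        out["general_health"] = rating
        out["poor_health"] = measures.poor_health(rating)
    if "sf12_physical_latent" in out:
        out["sf12_physical"] = out["sf12_physical_latent"]
    if "sf12_mental_latent" in out:
        out["sf12_mental"] = out["sf12_mental_latent"]
    if "cesd_risk_latent" in out:
        risk = out["cesd_risk_latent"].to_numpy()
        totals = np.where(
            risk == 1,
            measures.CESD_RISK_CUTOFF + rng.binomial(13, 0.25, size=n),
            rng.binomial(7, 0.35, size=n),
        )
        items = np.vstack([cesd_items_from_total(t, rng) for t in totals])
        for j in range(7):
            out[f"cesd_item{j + 1}"] = items[:, j]
        derived = measures.cesd_score_frame(
            out[[f"cesd_item{j + 1}" for j in range(7)]]
        )
        out["cesd_score"] = derived["cesd_score"]
        out["cesd_risk"] = derived["cesd_risk"]
    return out


# ---------------------------------------------------------------------------
# bundles and missingness
# ---------------------------------------------------------------------------


def generate_bundle(
    n: int,
    seed: int,
    archetypes: list[ArchetypeSpec] | None = None,
    covariate_config: CovariateConfig | None = None,
    effects: list[EffectSpec] | None = None,
) -> SyntheticPanelBundle:
    """Full synthetic panel: sequences, covariates, outcomes, truth labels."""
    if archetypes is None:
        archetypes = default_archetypes()
    panel, labels = generate_sequences(archetypes, n, seed)
    covariates = generate_covariates(labels, covariate_config, seed)
    outcomes = generate_outcomes(labels, covariates, effects, seed)
    return SyntheticPanelBundle(
        sequences=panel,
        covariates=covariates,
        outcomes=outcomes,
        truth=labels,
        seed=seed,
    )


def inject_missingness(
    bundle: SyntheticPanelBundle,
    rates: dict | None = None,
    seed: int = 0,
    biennial: bool = False,
) -> SyntheticPanelBundle:
    """Missing-completely-at-random masking of outcome/covariate columns.

    ``rates`` maps a column name (or the group keys ``"outcomes"`` /
    ``"covariates"``) to a missingness probability.  With
    ``biennial=True`` the sequence grid additionally drops every other age
    from 35 on, emulating the survey's switch from annual to biennial
    interviews; those design gaps are recoverable by ``fill_gaps``.
    """
    rates = dict(rates or {})
    for key, r in rates.items():
        if not 0 <= r <= 1:
            raise ValueError(f"missingness rate for {key!r} outside [0, 1]")
    rng = _stream(seed if bundle.seed is None else bundle.seed, 4)
    outcomes = bundle.outcomes.copy()
    covariates = bundle.covariates.copy()
    n = bundle.n

    def _mask(frame, col, rate):
        if rate > 0:
            frame.loc[rng.random(n) < rate, col] = np.nan

    for col in outcomes.columns:
        rate = rates.get(col, rates.get("outcomes", 0.0))
        _mask(outcomes, col, rate)
    for col in covariates.columns:
        rate = rates.get(col, rates.get("covariates", 0.0))
        _mask(covariates, col, rate)

    codes = bundle.sequences.codes.copy()
    if biennial:
        gap_ages = [a for a in range(35, 50, 2)]
        for a in gap_ages:
            codes[:, a - 22] = MISSING
    seq_rate = rates.get("sequences", 0.0)
    if seq_rate > 0:
        codes[rng.random(codes.shape) < seq_rate] = MISSING
    panel = SequencePanel(
        ids=bundle.sequences.ids.copy(), codes=codes, alphabet=bundle.sequences.alphabet
    )
    return SyntheticPanelBundle(
        sequences=panel,
        covariates=covariates,
        outcomes=outcomes,
        truth=None if bundle.truth is None else bundle.truth.copy(),
        seed=bundle.seed,
    )
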