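"""Scale construction and classification rules for the age-50 health outcomes.

Implements the survey-derived measures: the five-state work-schedule
classifier, the weekly sleep-hours composite, the standardized sleep-quality
score with Cronbach's alpha, the 7-item CES-D short form (0-21, clinical-risk
cutoff >= 8), the fair/poor self-rated-health indicator, and the
proportion-of-years classifications of weekly hours and occupation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# -- work-schedule states ----------------------------------------------------

#: minutes since midnight for the clock boundaries of the schedule windows
_SIX_AM = 6 * 60
_EIGHT_AM = 8 * 60
_TWO_PM = 14 * 60
_SIX_PM = 18 * 60
_NINE_PM = 21 * 60
_MIDNIGHT = 24 * 60


@dataclass(frozen=True)
class ScheduleObservation:
    """One survey report of usual work timing.

    ``start_time``/``end_time`` are clock times in minutes since midnight
    (0-1439); an end at or before the start denotes a shift wrapping past
    midnight.  ``irregular_flag`` marks split/rotating/irregular hours,
    ``not_working_flag`` marks no job at the survey date.
    """

    start_time: int
    end_time: int
    irregular_flag: bool = False
    not_working_flag: bool = False

    def __post_init__(self) -> None:
        for t in (self.start_time, self.end_time):
            if not (0 <= t <= 1439):
                raise ValueError(f"clock time {t} outside [0, 1439]")


def classify_schedule(obs: ScheduleObservation) -> str:
    """Map a schedule observation to one of ``NW, ST, EV, NI, VH``.

    First-match precedence (the clock windows overlap):

    1. ``NW`` if not working;
    2. ``VH`` if split/rotating/irregular hours;
    3. ``ST`` (standard): starts 6 a.m. or later and ends by 6 p.m. same day;
    4. ``EV`` (evening): starts 2 p.m. or later and ends by midnight;
    5. ``NI`` (night): starts 9 p.m. or later, or ends by 8 a.m.;
    6. ``VH`` otherwise (hours fitting no window).
    """
    if obs.not_working_flag:
        return "NW"
    if obs.irregular_flag:
        return "VH"
    start, end = obs.start_time, obs.end_time
    wraps = end <= start and not (start == 0 and end == 0)
    end_eff = end + _MIDNIGHT if wraps else end  # effective end on a 0-2880 axis
    if not wraps and start >= _SIX_AM and end <= _SIX_PM:
        return "ST"
    if start >= _TWO_PM and end_eff <= _MIDNIGHT:
        return "EV"
    if start >= _NINE_PM or (end % _MIDNIGHT) <= _EIGHT_AM:
        return "NI"
    return "VH"


# -- sleep ------------------------------------------------------------------


def weekly_sleep_average(
    weekday_hours, weekend_hours, formula: str = "mean2"
):
    """Average sleep hours per day across a 7-day week.

    ``mean2`` (default) is the unweighted mean of the weekday and weekend
    reports; ``weighted52`` weights them 5:2.  Accepts scalars or arrays;
    missing inputs propagate to a missing result.
    """
    wd = np.asarray(weekday_hours, dtype=float)
    we = np.asarray(weekend_hours, dtype=float)
    with np.errstate(invalid="ignore"):
        if ((wd < 0) | (wd > 24)).any() or ((we < 0) | (we > 24)).any():
            raise ValueError("sleep hours must lie in [0, 24]")
    if formula == "mean2":
        out = (wd + we) / 2.0
    elif formula == "weighted52":
        out = (5.0 * wd + 2.0 * we) / 7.0
    else:
        raise ValueError(f"unknown formula {formula!r}")
    if out.ndim == 0:
        return float(out)
    return out


def weekly_sleep_gap(per_day_a: float, per_day_b: float) -> float:
    """Hours-per-week gap implied by two per-day sleep averages."""
    return (per_day_a - per_day_b) * 7.0


def sleep_quality_score(
    items: pd.DataFrame, reverse: bool = True
) -> tuple[pd.Series, float]:
    """Standardized sleep-quality score plus Cronbach's alpha.

    ``items`` holds the four 1-4 Likert reports of sleep problems (trouble
    falling asleep, waking with trouble returning to sleep, waking too early,
    feeling unrested).  With ``reverse=True`` (the default) items are flipped
    to ``5 - item`` so that higher = better quality, averaged per person, and
    z-standardized over the persons with complete items (mean 0, sd 1 within
    that cohort).  Persons with any missing item get a missing score.
    """
    x = items.to_numpy(dtype=float)
    if x.shape[1] != 4:
        raise ValueError("expected exactly four sleep-quality items")
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(x) & ((x < 1) | (x > 4))
    if bad.any():
        raise ValueError("sleep-quality items must lie in {1,2,3,4}")
    if reverse:
        x = 5.0 - x
    complete = ~np.isnan(x).any(axis=1)
    if complete.sum() < 2:
        raise ValueError("need at least two persons with complete items")
    raw = x[complete].mean(axis=1)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("zero variance in raw sleep-quality scores; "
                         "standardized score undefined")
    scores = np.full(x.shape[0], np.nan)
    scores[complete] = (raw - raw.mean()) / sd
    alpha = cronbach_alpha(x[complete])
    return pd.Series(scores, index=items.index, name="sleep_quality"), alpha


def cronbach_alpha(items: np.ndarray) -> float:
    """Cronbach's alpha for an ``(n, k)`` complete item matrix."""
    items = np.asarray(items, dtype=float)
    k = items.shape[1]
    item_var = items.var(axis=0, ddof=1).sum()
    total_var = items.sum(axis=1).var(ddof=1)
    return k / (k - 1) * (1.0 - item_var / total_var)


# -- depression -------------------------------------------------------------

CESD_MAX: int = 21
CESD_RISK_CUTOFF: int = 8


def cesd_score(items) -> tuple[float, float]:
    """Total 7-item CES-D score (0-21) and the clinical-risk flag.

    Returns ``(score, at_risk)``; both are NaN when any item is missing
    (the scale is coded missing if one item is missing).  ``at_risk`` is
    1.0 when the score reaches the >= 8 cutoff.
    """
    x = np.asarray(items, dtype=float)
    if x.shape[-1] != 7:
        raise ValueError("expected exactly seven CES-D items")
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(x) & ((x < 0) | (x > 3) | (x != np.floor(x)))
    if bad.any():
        raise ValueError("CES-D items must lie in {0,1,2,3}")
    if np.isnan(x).any():
        return float("nan"), float("nan")
    score = float(x.sum())
    return score, float(score >= CESD_RISK_CUTOFF)


def cesd_score_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Vectorized CES-D scoring over a cohort item table."""
    x = items.to_numpy(dtype=float)
    if x.shape[1] != 7:
        raise ValueError("expected exactly seven CES-D items")
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(x) & ((x < 0) | (x > 3) | (x != np.floor(x)))
    if bad.any():
        raise ValueError("CES-D items must lie in {0,1,2,3}")
    score = x.sum(axis=1)
    score[np.isnan(x).any(axis=1)] = np.nan
    risk = np.where(np.isnan(score), np.nan, (score >= CESD_RISK_CUTOFF).astype(float))
    return pd.DataFrame({"cesd_score": score, "cesd_risk": risk}, index=items.index)


# -- general health ---------------------------------------------------------


def poor_health(self_rating) -> float:
    """1 if self-rated general health is fair (4) or poor (5), else 0.

    The rating runs 1 = excellent ... 5 = poor; NaN propagates.
    """
    r = np.asarray(self_rating, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = ~np.isnan(r) & ~np.isin(r, [1, 2, 3, 4, 5])
    if bad.any():
        raise ValueError("general-health rating must lie in {1..5}")
    out = np.where(np.isnan(r), np.nan, (r >= 4).astype(float))
    if out.ndim == 0:
        return float(out)
    return out


# -- proportion-of-years exposure classifications ---------------------------

FULL_TIME_HOURS: float = 35.0


def classify_weekly_hours(hours) -> str:
    """Classify a weekly-hours history into full-time / part-time / mixed.

    A survey year counts as full-time at >= 35 hours, part-time below;
    years with zero hours (not working) are excluded from the denominator.
    The category whose share of worked years reaches 0.50 *and* exceeds the
    other wins; equal shares (or no worked years) give ``mixed``.
    """
    h = np.asarray(hours, dtype=float)
    h = h[~np.isnan(h)]
    if h.size == 0:
        raise ValueError("no observed years")
    if (h < 0).any():
        raise ValueError("weekly hours must be nonnegative")
    worked = h[h > 0]
    if worked.size == 0:
        return "mixed"
    p_full = (worked >= FULL_TIME_HOURS).mean()
    p_part = 1.0 - p_full
    if p_full >= 0.5 and p_full > p_part:
        return "mostly_full_time"
    if p_part >= 0.5 and p_part > p_full:
        return "mostly_part_time"
    return "mixed"


OCCUPATION_CATEGORIES: tuple[str, ...] = (
    "professional_managerial",
    "sales",
    "service",
    "other",
)


def classify_occupation(occupations, vocabulary=OCCUPATION_CATEGORIES) -> str:
    """Primary occupation category over the observed survey years.

    The category held for at least half of the observed years wins
    (inclusive 0.50); with no majority category the history is ``mixed``.
    """
    if not vocabulary:
        raise ValueError("empty occupation vocabulary")
    occ = [o for o in occupations if not pd.isna(o)]
    if not occ:
        raise ValueError("no observed years")
    unknown = set(occ) - set(vocabulary)
    if unknown:
        raise ValueError(f"occupations outside vocabulary: {sorted(unknown)}")
    counts = pd.Series(occ).value_counts()
    share = counts / len(occ)
    top = share.idxmax()
    if share.loc[top] >= 0.5:
        return f"mostly_{top}"
    return "mixed"


# -- cohort filtering -------------------------------------------------------


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts from the cohort filter."""

    start_n: int
    missing_outcome: int = 0
    missing_sequence: int = 0
    missing_covariates: int = 0

    @property
    def retained(self) -> int:
        return (
            self.start_n
            - self.missing_outcome
            - self.missing_sequence
            - self.missing_covariates
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "start",
                    "missing_outcome",
                    "missing_sequence",
                    "missing_covariates",
                    "retained",
                ],
                "n": [
                    self.start_n,
                    self.missing_outcome,
                    self.missing_sequence,
                    self.missing_covariates,
                    self.retained,
                ],
            }
        )


def cohort_filter(bundle, outcome: str, covariates: list[str] | None = None):
    """Listwise-complete analysis cohort for one target outcome.

    Sequentially drops persons missing the target outcome, persons whose
    state sequence is entirely missing (unfillable), and persons missing any
    requested covariate.  Returns ``(filtered bundle, ExclusionLog)``.
    """
    from .synth import SyntheticPanelBundle  # local import to avoid a cycle

    n0 = bundle.sequences.n
    log = ExclusionLog(start_n=n0)
    keep = np.ones(n0, dtype=bool)

    if outcome not in bundle.outcomes.columns:
        raise KeyError(f"outcome {outcome!r} not in the outcomes table")
    miss_out = bundle.outcomes[outcome].isna().to_numpy()
    log.missing_outcome = int((keep & miss_out).sum())
    keep &= ~miss_out

    seq_all_missing = (bundle.sequences.codes == -1).all(axis=1)
    log.missing_sequence = int((keep & seq_all_missing).sum())
    keep &= ~seq_all_missing

    cov_cols = list(covariates) if covariates is not None else list(
        bundle.covariates.columns
    )
    miss_cov = bundle.covariates[cov_cols].isna().any(axis=1).to_numpy()
    log.missing_covariates = int((keep & miss_cov).sum())
    keep &= ~miss_cov

    filtered = SyntheticPanelBundle(
        sequences=bundle.sequences.subset(keep),
        covariates=bundle.covariates.loc[keep],
        outcomes=bundle.outcomes.loc[keep],
        truth=bundle.truth.loc[keep] if bundle.truth is not None else None,
        seed=bundle.seed,
    )
    return filtered, log
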