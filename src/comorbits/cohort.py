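"""Cohort construction: injury severity, eligibility, exact 1:1 matching.

Severity follows standard clinical thresholds: loss of consciousness (LOC)
of 0-30 minutes or alteration of consciousness / post-traumatic amnesia
(AOC/PTA) of 0-1 day is mild; LOC > 30 minutes or AOC/PTA > 1 day is
moderate/severe; any penetrating injury is penetrating.  When several injury
records are present the highest severity wins
(penetrating > moderate_severe > mild > unclassified).

Exposed subjects are eligible when their index year falls in the configured
range, they have at least two years of care engagement, and their
observation window covers the full +/-72-month analysis window around the
index month.  Eligible cases are exactly matched 1:1 with unique controls on
(age at index in completed years, sex, race, ethnicity); each matched
control inherits its case's index month.  Matching is greedy over a
seed-shuffled pool, so it is deterministic given input order and seed;
cases without an exact twin are returned unmatched (and dropped with a
warning by the pipeline, not an error).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeutil import parse_month

__all__ = [
    "SEVERITY_ORDER",
    "InjuryRecord",
    "classify_severity",
    "apply_eligibility",
    "exact_match",
    "assign_control_index",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)

SEVERITY_ORDER = ("unclassified", "mild", "moderate_severe", "penetrating")
_RANK = {s: i for i, s in enumerate(SEVERITY_ORDER)}

MATCH_KEYS = ["age_at_index", "sex", "race", "ethnicity"]


@dataclass(frozen=True)
class InjuryRecord:
    """One injury-event record: LOC minutes, AOC/PTA days (either may be
    missing), and whether the injury was penetrating."""

    loc_minutes: float | None = None
    aoc_pta_days: float | None = None
    penetrating: bool = False

    def __post_init__(self):
        for v in (self.loc_minutes, self.aoc_pta_days):
            if v is not None and v < 0:
                raise ValueError("injury durations must be non-negative")


def _record_severity(rec: InjuryRecord) -> str:
    if rec.penetrating:
        return "penetrating"
    loc, aoc = rec.loc_minutes, rec.aoc_pta_days
    if (loc is not None and loc > 30) or (aoc is not None and aoc > 1):
        return "moderate_severe"
    if loc is not None or aoc is not None:
        return "mild"
    return "unclassified"


def classify_severity(records: list[InjuryRecord]) -> str:
    """Highest severity across injury records."""
    if not records:
        raise ValueError("at least one injury record is required")
    return max((_record_severity(r) for r in records), key=_RANK.__getitem__)


def apply_eligibility(
    subjects: pd.DataFrame,
    index_years: tuple[int, int] = (2008, 2017),
    window: int = 72,
    min_engagement_years: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter exposed subjects; controls pass through to the matching pool.

    Returns (eligible subjects, exclusion log with one reason per exclusion).
    Exclusion reasons: ``index_window`` (index year outside range),
    ``engagement`` (< 2 years of care), ``coverage`` (observation window does
    not span index +/- ``window`` months).
    """
    required = {"group", "index_month", "engagement_years",
                "observation_start", "observation_end"}
    missing = required - set(subjects.columns)
    if missing:
        raise ValueError(f"subject table missing fields: {sorted(missing)}")

    reasons = []
    keep = np.ones(len(subjects), dtype=bool)
    for i, row in enumerate(subjects.itertuples(index=False)):
        if row.group != "exposed":
            continue
        idx = parse_month(row.index_month)
        year = idx // 12
        if not index_years[0] <= year <= index_years[1]:
            keep[i] = False
            reasons.append((row.subject_id, "index_window"))
        elif float(row.engagement_years) < min_engagement_years:
            keep[i] = False
            reasons.append((row.subject_id, "engagement"))
        elif (parse_month(row.observation_start) > idx - window
              or parse_month(row.observation_end) < idx + window):
            keep[i] = False
            reasons.append((row.subject_id, "coverage"))
    log = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    return subjects[keep].reset_index(drop=True), log


def exact_match(
    cases: pd.DataFrame, pool: pd.DataFrame, seed: int = 0, window: int = 72
) -> tuple[pd.DataFrame, list[str]]:
    """Greedy exact 1:1 matching of cases to unique controls.

    Case and pool id sets must be disjoint.  Controls must match the case
    exactly on age (completed years), sex, race and ethnicity, and — when
    observation columns are present — their observation window must cover the
    case's index +/- ``window`` months.  Each matched control inherits the
    case's index month.  Returns (pairs, unmatched case ids).
    """
    if set(cases["subject_id"]) & set(pool["subject_id"]):
        raise ValueError("case and pool subject ids overlap")

    rng = np.random.default_rng(seed)
    shuffled = pool.iloc[rng.permutation(len(pool))]
    buckets: dict[tuple, list] = {}
    has_obs = {"observation_start", "observation_end"} <= set(pool.columns)
    for row in shuffled.itertuples(index=False):
        key = (int(row.age_at_index), row.sex, row.race, row.ethnicity)
        obs = (
            (parse_month(row.observation_start), parse_month(row.observation_end))
            if has_obs else None
        )
        buckets.setdefault(key, []).append((row.subject_id, obs))

    pairs, unmatched = [], []
    for row in cases.itertuples(index=False):
        key = (int(row.age_at_index), row.sex, row.race, row.ethnicity)
        idx = parse_month(row.index_month)
        bucket = buckets.get(key, [])
        chosen = None
        for j, (cid, obs) in enumerate(bucket):
            if obs is None or (obs[0] <= idx - window and obs[1] >= idx + window):
                chosen = j
                break
        if chosen is None:
            unmatched.append(row.subject_id)
        else:
            cid, _ = bucket.pop(chosen)
            pairs.append((row.subject_id, cid, row.index_month))
    if unmatched:
        logger.warning("%d cases had no exact-match control and were dropped",
                       len(unmatched))
    return (
        pd.DataFrame(pairs, columns=["case_id", "control_id", "index_month"]),
        unmatched,
    )


def assign_control_index(
    subjects: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Matched-cohort subject table: paired cases and controls only, with
    each control's index month set to its case's index month."""
    inherit = dict(zip(pairs["control_id"], pairs["index_month"]))
    keep = set(pairs["case_id"]) | set(pairs["control_id"])
    cohort = subjects[subjects["subject_id"].isin(keep)].copy()
    mask = cohort["subject_id"].isin(inherit)
    cohort.loc[mask, "index_month"] = cohort.loc[mask, "subject_id"].map(inherit)
    return cohort.reset_index(drop=True)


def summarize_cohort(subjects: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Descriptive counts/percentages by group for each covariate, plus
    severity within the exposed group (matched covariates are identical in
    both groups by construction)."""
    cohort = assign_control_index(subjects, pairs)
    if cohort.empty:
        raise ValueError("empty cohort")
    rows = []
    for group, sub in cohort.groupby("group"):
        n = len(sub)
        rows.append({"group": group, "covariate": "n", "level": "", "count": n,
                     "percent": 100.0})
        rows.append({"group": group, "covariate": "age_at_index",
                     "level": "mean", "count": n,
                     "percent": float(sub["age_at_index"].mean())})
        for cov in ["sex", "race", "ethnicity", "severity"]:
            if cov == "severity" and group != "exposed":
                continue
            counts = sub[cov].value_counts()
            for level, c in counts.items():
                rows.append({"group": group, "covariate": cov, "level": level,
                             "count": int(c), "percent": 100.0 * c / n})
    return pd.DataFrame(rows).sort_values(
        ["covariate", "level", "group"], kind="stable"
    ).reset_index(drop=True)
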