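"""Diagnosis ascertainment from raw code events.

A subject is considered diagnosed with a condition only when at least two of
that condition's code dates are separated by one ITS time step — 30 days or
more (threshold inclusive, configurable).  Because dates are totally
ordered, such a pair exists iff the span between the earliest and latest
code reaches the threshold.  The onset month is, by default, the month of
the earliest code participating in a qualifying pair (which is the earliest
code overall whenever the rule is met); ``onset_rule="second"`` instead
dates onset at the earliest confirming code, i.e. the first code at least
the threshold after the earliest one.

Codes before a subject's observation start are ignored; repeated same-day
codes count once.  Conditions with no pre-index onset evidence in either
group are excluded from analysis downstream (:func:`filter_conditions`).
"""

from __future__ import annotations

import pandas as pd

from .timeutil import month_offset, parse_month

__all__ = ["ascertain_diagnoses", "filter_conditions"]


def ascertain_diagnoses(
    events: pd.DataFrame,
    subjects: pd.DataFrame,
    min_separation_days: int = 30,
    onset_rule: str = "first",
) -> pd.DataFrame:
    """Apply the two-code rule; return onsets (one row per subject x condition).

    Output columns: ``subject_id``, ``condition_id``, ``onset_month_offset``
    (months relative to the subject's index month, index month = 0).
    """
    if onset_rule not in ("first", "second"):
        raise ValueError("onset_rule must be 'first' or 'second'")
    known = set(subjects["subject_id"])
    unknown = set(events["subject_id"]) - known
    if unknown:
        raise ValueError(f"events reference unknown subjects: {sorted(unknown)[:5]}")

    meta = subjects.set_index("subject_id")
    index_month = meta["index_month"].map(parse_month)
    obs_start = (
        meta["observation_start"].map(parse_month)
        if "observation_start" in meta.columns
        else None
    )

    ev = events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"]).dt.date
    rows = []
    for (sid, cond), grp in ev.groupby(["subject_id", "condition_id"], sort=True):
        dates = sorted(set(grp["event_date"]))
        if obs_start is not None:
            start = obs_start[sid]
            dates = [d for d in dates if parse_month(d.isoformat()) >= start]
        if len(dates) < 2:
            continue
        if (dates[-1] - dates[0]).days < min_separation_days:
            continue
        if onset_rule == "first":
            onset_date = dates[0]
        else:
            onset_date = next(
                d for d in dates[1:]
                if (d - dates[0]).days >= min_separation_days
            )
        rows.append((sid, cond, month_offset(onset_date, index_month[sid])))
    return pd.DataFrame(
        rows, columns=["subject_id", "condition_id", "onset_month_offset"]
    )


def filter_conditions(
    onsets: pd.DataFrame,
    subjects: pd.DataFrame,
    condition_list: list[str],
) -> tuple[list[str], pd.DataFrame]:
    """Keep conditions with pre-index diagnosis evidence in either group.

    A condition is retained iff it has at least one onset at a negative
    month offset among exposed subjects or among controls.  Returns the
    retained list (input order preserved) and an exclusion log.
    """
    if not condition_list:
        raise ValueError("condition_list must be non-empty")
    in_cohort = onsets["subject_id"].isin(set(subjects["subject_id"]))
    pre = onsets[in_cohort & (onsets["onset_month_offset"] < 0)]
    evidenced = set(pre["condition_id"])
    retained = [c for c in condition_list if c in evidenced]
    excluded = pd.DataFrame(
        [(c, "no_pre_index_evidence") for c in condition_list if c not in evidenced],
        columns=["condition_id", "reason"],
    )
    return retained, excluded
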