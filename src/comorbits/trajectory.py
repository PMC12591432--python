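"""Monthly prevalence and incidence trajectories around the index month.

Prevalence here is cumulative: the percent of a fixed group ever diagnosed
by each monthly offset in a +/-72-month window centered on the index month
(closed cohort, fixed denominator).  Onsets earlier than the window's left
edge count toward every value; onsets after the right edge are ignored.
Incidence is the first difference of prevalence, in percent of the group
newly diagnosed per month.

The wide prevalence matrix layout (one row per condition x group, one
column per month offset) mirrors the deposited-summary-spreadsheet style:
readable and writable as CSV or XLSX, tolerant of shuffled columns and of
offset headers written as bare integers, "m+3"/"month -12", or
"year -6"-style labels (years are converted to months).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PrevalenceSeries",
    "IncidenceSeries",
    "prevalence_series",
    "incidence_series",
    "group_subject_ids",
    "save_prevalence_matrix",
    "load_prevalence_matrix",
]

GROUPS = ("control", "mild", "moderate_or_above", "all_tbi")

#: monotonicity slack (percentage points) tolerated when validating files
ROUNDING_TOL = 0.05


@dataclass
class PrevalenceSeries:
    """Cumulative percent-ever-diagnosed for one condition x group."""

    condition_id: str
    group: str
    offsets: np.ndarray
    values: np.ndarray
    group_size: int

    def value_at(self, offset: int) -> float:
        pos = np.nonzero(self.offsets == offset)[0]
        if pos.size == 0:
            raise KeyError(f"offset {offset} not in series")
        return float(self.values[pos[0]])


@dataclass
class IncidenceSeries:
    """Percent of the group newly diagnosed per month (first difference)."""

    condition_id: str
    group: str
    offsets: np.ndarray
    values: np.ndarray
    group_size: int


def group_subject_ids(subjects: pd.DataFrame, pairs: pd.DataFrame, group: str):
    """Subject ids belonging to an analysis group.

    ``control``: matched controls; ``all_tbi``: all matched cases; ``mild``:
    matched cases with mild severity; ``moderate_or_above``: moderate/severe
    or penetrating cases (unclassified contributes to ``all_tbi`` only).
    """
    if group == "control":
        return list(pairs["control_id"])
    cases = subjects[subjects["subject_id"].isin(set(pairs["case_id"]))]
    if group == "all_tbi":
        return list(cases["subject_id"])
    if group == "mild":
        return list(cases.loc[cases["severity"] == "mild", "subject_id"])
    if group == "moderate_or_above":
        sel = cases["severity"].isin(["moderate_severe", "penetrating"])
        return list(cases.loc[sel, "subject_id"])
    raise ValueError(f"unknown group: {group}")


def prevalence_series(
    onsets: pd.DataFrame,
    subject_ids,
    condition_id: str,
    group: str,
    window: int = 72,
) -> PrevalenceSeries:
    """Cumulative prevalence on the offset grid -window..+window.

    A condition absent from the onset table yields an all-zero series; an
    empty group is an error (no denominator).
    """
    ids = list(subject_ids)
    if not ids:
        raise ValueError("empty group")
    sel = onsets[
        (onsets["condition_id"] == condition_id)
        & onsets["subject_id"].isin(set(ids))
    ]
    offsets = np.arange(-window, window + 1)
    counts = np.zeros(offsets.size, dtype=float)
    offs = sel["onset_month_offset"].to_numpy()
    offs = offs[offs <= window]
    if offs.size:
        clipped = np.clip(offs, -window, window)
        counts = np.bincount(clipped + window, minlength=offsets.size).astype(float)
    values = 100.0 * np.cumsum(counts) / len(ids)
    return PrevalenceSeries(condition_id, group, offsets, values, len(ids))


def incidence_series(prev: PrevalenceSeries) -> IncidenceSeries:
    """First difference of a prevalence series (offsets -window+1..+window)."""
    return IncidenceSeries(
        prev.condition_id,
        prev.group,
        prev.offsets[1:].copy(),
        np.diff(prev.values),
        prev.group_size,
    )


# -- wide matrix IO -------------------------------------------------------

def _series_frame(series_list) -> pd.DataFrame:
    offsets = series_list[0].offsets
    rows = {}
    sizes = {}
    for s in series_list:
        if not np.array_equal(s.offsets, offsets):
            raise ValueError("all series must share one offset grid")
        rows[(s.condition_id, s.group)] = s.values
        sizes[(s.condition_id, s.group)] = s.group_size
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[str(o) for o in offsets])
    df.insert(0, "group_size", [sizes[k] for k in df.index])
    df.index = pd.MultiIndex.from_tuples(df.index, names=["condition_id", "group"])
    return df.reset_index()


def save_prevalence_matrix(series_list, path: str | Path) -> Path:
    """Write series as a wide CSV or XLSX (by file extension)."""
    path = Path(path)
    df = _series_frame(list(series_list))
    if path.suffix.lower() in (".xlsx", ".xls"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
    return path


_OFFSET_PAT = re.compile(
    r"^\s*(?:(?P<unit>year|yr|y|month|mon|m)\s*)?(?P<num>[+-]?\d+(?:\.\d+)?)\s*$",
    re.IGNORECASE,
)


def _parse_offset_label(label) -> int | None:
    m = _OFFSET_PAT.match(str(label).replace("_", " "))
    if not m:
        return None
    num = float(m.group("num"))
    unit = (m.group("unit") or "m").lower()
    months = num * 12 if unit.startswith("y") else num
    if abs(months - round(months)) > 1e-9:
        return None
    return int(round(months))


def load_prevalence_matrix(path: str | Path) -> list[PrevalenceSeries]:
    """Read a wide prevalence matrix written by :func:`save_prevalence_matrix`
    (or an equivalent spreadsheet).

    Offset columns may appear in any order.  Monotonicity violations larger
    than the 0.05-percentage-point rounding tolerance raise a warning, not an
    error.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)

    offset_cols = {}
    for col in df.columns:
        if str(col).lower() in ("condition_id", "condition", "group", "group_size", "n"):
            continue
        off = _parse_offset_label(col)
        if off is not None:
            offset_cols[col] = off
    if not offset_cols:
        raise ValueError(f"no month-offset columns found in {path}")

    cond_col = next(
        (c for c in df.columns if str(c).lower() in ("condition_id", "condition")), None
    )
    group_col = next((c for c in df.columns if str(c).lower() == "group"), None)
    if cond_col is None or group_col is None:
        raise ValueError("matrix must have condition and group columns")
    size_col = next(
        (c for c in df.columns if str(c).lower() in ("group_size", "n")), None
    )

    ordered = sorted(offset_cols.items(), key=lambda kv: kv[1])
    offsets = np.asarray([o for _, o in ordered])
    series = []
    for _, row in df.iterrows():
        values = np.asarray([float(row[c]) for c, _ in ordered])
        if np.any(np.diff(values) < -ROUNDING_TOL):
            import warnings

            warnings.warn(
                f"prevalence for {row[cond_col]}/{row[group_col]} is not "
                "monotone beyond rounding tolerance"
            )
        series.append(
            PrevalenceSeries(
                condition_id=str(row[cond_col]),
                group=str(row[group_col]),
                offsets=offsets.copy(),
                values=values,
                group_size=int(row[size_col]) if size_col is not None else 0,
            )
        )
    return series
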