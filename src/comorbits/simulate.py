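"""Synthetic matched-cohort simulator.

Generates a subject table and a longitudinal diagnosis-code event stream with
the statistical structure the downstream interrupted-time-series analysis
assumes:

* a per-condition baseline monthly onset hazard shared by exposed and control
  subjects before the index month,
* an exposure-only extra onset probability concentrated in the index month
  (the acute "spike" that drives the index-month incidence rate),
* an exposure-only step change in the monthly onset hazard after the index
  month (which bends the cumulative prevalence curve and drives the annual
  incidence-rate difference),
* a mild secular trend applied to both groups, and
* demographics (age, sex, race, ethnicity) drawn so that every exposed
  subject has at least one exact demographic twin in the control pool.

Onset is an absorbing state per subject and condition: prevalence downstream
is "percent ever diagnosed".  After onset the simulator emits dated codes,
including a guaranteed confirmation code at least 30 days after the first,
so the two-code ascertainment rule recovers true onsets by default.

Randomness is one shared stream split per subject by a counter
(``SeedSequence(seed, spawn_key=(1, subject_counter, condition_counter))``),
so adding a condition or enlarging the cohort never perturbs the events of
existing subject/condition pairs.

Ground truth is written to a sidecar ``truth.json``: for each condition the
exact expected prevalence curve (a deterministic at-risk recursion) is
computed and the index-month incidence rate, incidence rate ratio, and the
annual incidence-rate-difference *estimand* (the slope-change coefficient of
the segmented regression fitted to the noiseless expected curve, times 12)
are recorded, alongside the nominal configured parameters.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .timeutil import int_to_month, month_to_int, parse_month

__all__ = [
    "ConditionProfile",
    "SimulationConfig",
    "generate_subjects",
    "generate_code_events",
    "expected_prevalence_curve",
    "compute_truth",
    "simulate_to_dir",
]

#: default demographic category probabilities (post-9/11 veteran cohort mix)
DEFAULT_SEX = {"M": 0.927, "F": 0.073}
DEFAULT_RACE = {"White": 0.773, "Black": 0.141, "Other": 0.086}
DEFAULT_ETHNICITY = {"Non-Hispanic": 0.851, "Hispanic": 0.149}
DEFAULT_SEVERITY = {
    "mild": 0.675,
    "moderate_severe": 0.140,
    "penetrating": 0.026,
    "unclassified": 0.159,
}


@dataclass(frozen=True)
class ConditionProfile:
    """Onset-hazard parameters for one simulated condition.

    Parameters
    ----------
    condition_id:
        Opaque condition label.
    baseline_hazard:
        Probability per month of first onset, shared by both groups before
        the index month.
    index_spike:
        Extra onset probability in the index month, exposed subjects only.
    post_slope_delta:
        Step increase in the monthly onset hazard for months strictly after
        the index month, exposed subjects only.
    code_rate:
        Mean extra codes per month emitted after onset (Poisson), on top of
        the onset code and its confirmation.
    guarantee_confirmation:
        Emit a second code 30-44 days after the onset code so the two-code
        rule always recovers a true onset.  Turn off to probe ascertainment
        sensitivity.
    coding_months:
        How many months after onset extra codes keep being emitted.
    """

    condition_id: str
    baseline_hazard: float = 0.001
    index_spike: float = 0.0
    post_slope_delta: float = 0.0
    code_rate: float = 0.5
    guarantee_confirmation: bool = True
    coding_months: int = 12

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_hazard <= 1.0:
            raise ValueError("baseline_hazard must be a probability")
        if not 0.0 <= self.index_spike <= 1.0:
            raise ValueError("index_spike must be a probability")
        if self.baseline_hazard + self.index_spike > 1.0:
            raise ValueError("baseline_hazard + index_spike must be <= 1")
        if self.baseline_hazard + self.post_slope_delta < 0.0:
            raise ValueError("post-index hazard must be non-negative")
        if self.code_rate < 0:
            raise ValueError("code_rate must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort- and condition-level simulation parameters.

    ``secular_slope`` is a relative trend in percent per year applied
    multiplicatively to every baseline hazard in both groups, anchored at the
    start of the simulated calendar window.
    """

    n_exposed: int
    n_control_pool: int
    seed: int = 0
    index_year_range: tuple[int, int] = (2008, 2017)
    sex_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX))
    race_probs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE))
    ethnicity_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY)
    )
    severity_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEVERITY)
    )
    age_mean: float = 30.1
    age_sd: float = 9.0
    age_min: int = 18
    age_max: int = 70
    condition_profiles: tuple[ConditionProfile, ...] = ()
    secular_slope: float = 1.0
    engagement_range: tuple[float, float] = (2.0, 12.0)
    window_months: int = 72

    def __post_init__(self) -> None:
        if self.n_exposed <= 0 or self.n_control_pool <= 0:
            raise ValueError("subject counts must be positive")
        if self.n_control_pool < self.n_exposed:
            raise ValueError("n_control_pool must be >= n_exposed")
        for name, probs in (
            ("sex", self.sex_probs),
            ("race", self.race_probs),
            ("ethnicity", self.ethnicity_probs),
            ("severity", self.severity_probs),
        ):
            if not probs:
                raise ValueError(f"empty demographic spec: {name}")
            if any(p < 0 or p > 1 for p in probs.values()):
                raise ValueError(f"{name} probabilities must be in [0, 1]")
        object.__setattr__(
            self, "condition_profiles", tuple(self.condition_profiles)
        )

    # -- calendar geometry ------------------------------------------------
    @property
    def calendar_start(self) -> int:
        """First simulated month: six years before the earliest index year."""
        return month_to_int(self.index_year_range[0] - 6, 1)

    @property
    def calendar_end(self) -> int:
        """Last simulated month: six years after the latest index year."""
        return month_to_int(self.index_year_range[1] + 6, 12)

    @property
    def n_months(self) -> int:
        return self.calendar_end - self.calendar_start + 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.get("simulation", raw)
        profiles = tuple(
            ConditionProfile(**p) for p in sim.pop("conditions", [])
        )
        if "index_year_range" in sim:
            sim["index_year_range"] = tuple(sim["index_year_range"])
        if "engagement_range" in sim:
            sim["engagement_range"] = tuple(sim["engagement_range"])
        return cls(condition_profiles=profiles, **sim)


def _categorical(rng: np.random.Generator, probs: dict[str, float], n: int):
    labels = list(probs)
    p = np.asarray([probs[k] for k in labels], dtype=float)
    p = p / p.sum()
    return np.asarray(labels, dtype=object)[rng.choice(len(labels), size=n, p=p)]


def generate_subjects(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Draw the exposed cohort and the control pool.

    Returns the subject table plus the ground-truth record (see
    :func:`compute_truth`).  The first ``n_exposed`` pool members are exact
    demographic twins of the exposed subjects so 1:1 exact matching can always
    succeed; the remainder of the pool is drawn iid from the same marginals.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    n_e, n_c = config.n_exposed, config.n_control_pool

    def draw_demographics(n: int) -> pd.DataFrame:
        age = np.rint(rng.normal(config.age_mean, config.age_sd, size=n))
        age = np.clip(age, config.age_min, config.age_max).astype(int)
        return pd.DataFrame(
            {
                "sex": _categorical(rng, config.sex_probs, n),
                "race": _categorical(rng, config.race_probs, n),
                "ethnicity": _categorical(rng, config.ethnicity_probs, n),
                "age_at_index": age,
            }
        )

    exposed = draw_demographics(n_e)
    exposed.insert(0, "subject_id", [f"T{i:06d}" for i in range(n_e)])
    exposed["group"] = "exposed"
    exposed["severity"] = _categorical(rng, config.severity_probs, n_e)
    y0, y1 = config.index_year_range
    index_months = rng.integers(
        month_to_int(y0, 1), month_to_int(y1, 12) + 1, size=n_e
    )
    exposed["index_month"] = [int_to_month(m) for m in index_months]

    # twins of the exposed, then iid extras
    twins = exposed[["sex", "race", "ethnicity", "age_at_index"]].copy()
    extra = draw_demographics(n_c - n_e) if n_c > n_e else twins.iloc[:0]
    controls = pd.concat([twins, extra], ignore_index=True)
    controls.insert(0, "subject_id", [f"C{i:06d}" for i in range(n_c)])
    controls["group"] = "control"
    controls["severity"] = "none"
    controls["index_month"] = ""

    subjects = pd.concat([exposed, controls], ignore_index=True)
    lo, hi = config.engagement_range
    subjects["engagement_years"] = np.round(
        rng.uniform(lo, hi, size=len(subjects)), 2
    )
    subjects["observation_start"] = int_to_month(config.calendar_start)
    subjects["observation_end"] = int_to_month(config.calendar_end)
    cols = [
        "subject_id", "group", "severity", "sex", "race", "ethnicity",
        "age_at_index", "index_month", "engagement_years",
        "observation_start", "observation_end",
    ]
    return subjects[cols], compute_truth(config)


def _hazard_vector(profile: ConditionProfile, config: SimulationConfig) -> np.ndarray:
    """Baseline monthly hazard over the calendar window, with secular trend."""
    t_years = np.arange(config.n_months) / 12.0
    base = profile.baseline_hazard * (1.0 + config.secular_slope / 100.0 * t_years)
    return np.clip(base, 0.0, 1.0)


def _exposed_hazard(
    base: np.ndarray, profile: ConditionProfile, idx_pos: int
) -> np.ndarray:
    p = base.copy()
    p[idx_pos] += profile.index_spike
    p[idx_pos + 1:] += profile.post_slope_delta
    return np.clip(p, 0.0, 1.0)


def generate_code_events(
    subjects: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Realize onset times and dated code events for every subject/condition.

    Raises if the subject table does not match the config it was generated
    under (counts per group are checked).
    """
    n_e = int((subjects["group"] == "exposed").sum())
    n_c = int((subjects["group"] == "control").sum())
    if n_e != config.n_exposed or n_c != config.n_control_pool:
        raise ValueError(
            "subject table does not match config "
            f"(found {n_e} exposed / {n_c} control, "
            f"expected {config.n_exposed} / {config.n_control_pool})"
        )

    cal_start = config.calendar_start
    records: list[tuple[str, str, str]] = []
    sub_ids = subjects["subject_id"].to_numpy()
    groups = subjects["group"].to_numpy()
    idx_strings = subjects["index_month"].to_numpy()

    for ci, profile in enumerate(config.condition_profiles):
        base = _hazard_vector(profile, config)
        for si in range(len(subjects)):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(1, si, ci))
            )
            if groups[si] == "exposed":
                idx_pos = parse_month(idx_strings[si]) - cal_start
                p = _exposed_hazard(base, profile, idx_pos)
            else:
                p = base
            u = rng.random(config.n_months)
            hits = u < p
            if not hits.any():
                continue
            onset_pos = int(np.argmax(hits))
            records.extend(
                _emit_codes(rng, profile, config, sub_ids[si], onset_pos)
            )

    events = pd.DataFrame(records, columns=["subject_id", "condition_id", "event_date"])
    return events.sort_values(
        ["subject_id", "condition_id", "event_date"], kind="stable"
    ).reset_index(drop=True)


def _emit_codes(rng, profile, config, subject_id, onset_pos):
    cal_start = config.calendar_start
    onset_month = cal_start + onset_pos
    year, month0 = divmod(onset_month, 12)
    day = int(rng.integers(1, 29))
    first = _dt.date(year, month0 + 1, day)
    dates = [first]
    if profile.guarantee_confirmation:
        dates.append(first + _dt.timedelta(days=30 + int(rng.integers(0, 15))))
    last_pos = min(onset_pos + profile.coding_months, config.n_months - 1)
    for pos in range(onset_pos + 1, last_pos + 1):
        k = int(rng.poisson(profile.code_rate))
        if k:
            y, m0 = divmod(cal_start + pos, 12)
            for d in rng.integers(1, 29, size=k):
                dates.append(_dt.date(y, m0 + 1, int(d)))
    return [
        (subject_id, profile.condition_id, d.isoformat()) for d in dates
    ]


# -- exact expected curves (ground truth) ---------------------------------

def expected_prevalence_curve(
    profile: ConditionProfile,
    config: SimulationConfig,
    exposed: bool,
    index_month: int | None = None,
    window: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact expected cumulative prevalence (%) on the monthly offset grid.

    Computed by the deterministic at-risk recursion
    ``S(m) = S(m-1) * (1 - p(m))`` over the calendar window, then re-indexed
    to offsets around ``index_month`` (default: mid-range index month).
    """
    window = config.window_months if window is None else window
    if index_month is None:
        y0, y1 = config.index_year_range
        index_month = (month_to_int(y0, 1) + month_to_int(y1, 12)) // 2
    idx_pos = index_month - config.calendar_start
    base = _hazard_vector(profile, config)
    p = _exposed_hazard(base, profile, idx_pos) if exposed else base
    surv = np.cumprod(1.0 - p)
    prev = 100.0 * (1.0 - surv)
    offsets = np.arange(-window, window + 1)
    return offsets, prev[idx_pos + offsets]


def compute_truth(config: SimulationConfig) -> dict:
    """Per-condition ground truth for parameter-recovery tests.

    ``ir_index`` is the exact expected index-month prevalence increment in
    the exposed group; ``irr_index`` its ratio to the control increment (None
    when the control increment is zero); ``ird_annual`` the segmented
    regression slope-change estimand (12 x b3 on the exact expected curve).
    """
    from .its import SegmentedRegression  # local import: avoid cycle at import time

    truth: dict = {"conditions": {}, "config": _config_dict(config)}
    for profile in config.condition_profiles:
        offs, exp_curve = expected_prevalence_curve(profile, config, exposed=True)
        _, ctl_curve = expected_prevalence_curve(profile, config, exposed=False)
        ir_e = float(exp_curve[offs == 0][0] - exp_curve[offs == -1][0])
        ir_c = float(ctl_curve[offs == 0][0] - ctl_curve[offs == -1][0])
        entry = {
            "ir_index_pct_per_month": ir_e,
            "ir_index_control_pct_per_month": ir_c,
            "irr_index": (ir_e / ir_c) if ir_c > 0 else None,
            "nominal_ir_index_pct_per_month": 100.0 * profile.index_spike,
            "nominal_ird_annual_pct_per_year": 1200.0 * profile.post_slope_delta,
        }
        for label, curve in (("", exp_curve), ("_control", ctl_curve)):
            model = SegmentedRegression().fit(offs, curve)
            entry[f"ird_annual{label}_pct_per_year"] = (
                12.0 * model.coef_[3] if model.status_ == "ok" else None
            )
        truth["conditions"][profile.condition_id] = entry
    return truth


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["condition_profiles"] = [dataclasses.asdict(p) for p in config.condition_profiles]
    return d


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Run the simulator and write ``subjects.csv``, ``events.csv``, ``truth.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, truth = generate_subjects(config)
    events = generate_code_events(subjects, config)
    paths = {
        "subjects": out / "subjects.csv",
        "events": out / "events.csv",
        "truth": out / "truth.json",
    }
    subjects.to_csv(paths["subjects"], index=False)
    events.to_csv(paths["events"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
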