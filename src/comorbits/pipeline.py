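"""End-to-end pipeline: simulate -> build cohort -> ascertain -> trajectories
-> segmented fits -> metrics and reports.

Every stage writes its artifact to the output directory (subjects.csv,
events.csv, pairs.csv, exclusions, onsets.csv, prevalence matrix, fits.csv,
metrics.csv, ranked table) so stages can also be run and inspected
independently through the CLI.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import ascertain, cohort, metrics as metrics_mod, trajectory
from .its import fit_its
from .simulate import SimulationConfig, simulate_to_dir

__all__ = ["run_all", "analyze"]

logger = logging.getLogger(__name__)


def analyze(
    subjects: pd.DataFrame,
    events: pd.DataFrame,
    out_dir: str | Path,
    *,
    seed: int = 0,
    index_years: tuple[int, int] = (2008, 2017),
    window: int = 72,
    min_separation_days: int = 30,
    onset_rule: str = "first",
    top_k: int = 10,
    table_group: str = "all_tbi",
    plots: bool = False,
) -> dict:
    """Run the analysis stages on an existing subject/event pair of tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    eligible, exclusions = cohort.apply_eligibility(
        subjects, index_years=index_years, window=window
    )
    exclusions.to_csv(out / "exclusions_subjects.csv", index=False)

    cases = eligible[eligible["group"] == "exposed"]
    pool = eligible[eligible["group"] == "control"]
    pairs, unmatched = cohort.exact_match(cases, pool, seed=seed, window=window)
    pairs.to_csv(out / "pairs.csv", index=False)
    if unmatched:
        pd.DataFrame({"subject_id": unmatched, "reason": "no_exact_match"}).to_csv(
            out / "exclusions_unmatched.csv", index=False
        )

    matched = cohort.assign_control_index(eligible, pairs)
    summary = cohort.summarize_cohort(eligible, pairs)
    summary.to_csv(out / "cohort_summary.csv", index=False)

    ev = events[events["subject_id"].isin(set(matched["subject_id"]))]
    onsets = ascertain.ascertain_diagnoses(
        ev, matched, min_separation_days=min_separation_days, onset_rule=onset_rule
    )
    onsets.to_csv(out / "onsets.csv", index=False)

    condition_list = sorted(set(events["condition_id"]))
    retained, cond_excl = ascertain.filter_conditions(onsets, matched, condition_list)
    cond_excl.to_csv(out / "exclusions_conditions.csv", index=False)
    if not retained:
        logger.warning("no condition has pre-index evidence; nothing to fit")

    groups = {
        g: trajectory.group_subject_ids(matched, pairs, g)
        for g in trajectory.GROUPS
    }
    groups = {g: ids for g, ids in groups.items() if ids}

    series_list = [
        trajectory.prevalence_series(onsets, ids, cond, g, window=window)
        for cond in retained
        for g, ids in groups.items()
    ]
    trajectory.save_prevalence_matrix(series_list, out / "prevalence.csv")

    fits = {(s.condition_id, s.group): fit_its(s) for s in series_list}
    for (cond, grp), f in fits.items():
        if f.status != "ok":
            logger.warning("fit error for %s/%s", cond, grp)

    metric_table = metrics_mod.compute_metrics(series_list, fits)
    report_paths = metrics_mod.make_report(
        metric_table, fits, series_list, out,
        table_group=table_group, k=min(top_k, max(len(retained), 1)),
        plots=plots,
    )
    return {
        "pairs": pairs,
        "unmatched": unmatched,
        "matched_subjects": matched,
        "onsets": onsets,
        "retained_conditions": retained,
        "series": series_list,
        "fits": fits,
        "metrics": metric_table,
        "report_paths": report_paths,
        "summary": summary,
    }


def run_all(
    config: SimulationConfig,
    out_dir: str | Path,
    *,
    seed: int | None = None,
    **analysis_kwargs,
) -> dict:
    """Simulate a cohort under ``config`` and run the full analysis on it.

    ``seed`` overrides the config seed (it drives both simulation and the
    matching shuffle).
    """
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    out = Path(out_dir)
    simulate_to_dir(config, out)
    subjects = pd.read_csv(out / "subjects.csv", keep_default_na=False)
    events = pd.read_csv(out / "events.csv")
    result = analyze(
        subjects, events, out,
        seed=config.seed,
        index_years=config.index_year_range,
        window=config.window_months,
        **analysis_kwargs,
    )
    result["config"] = config
    return result
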