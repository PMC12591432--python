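"""Headline trajectory metrics, rankings, and report files.

Four metrics per condition x group, all on the percent (0-100) scale:

* ``prevalence_pre`` — percent ever diagnosed at offset -1, i.e. just before
  the index month (the index-month jump must not contaminate it);
* ``ir_index`` — incidence rate in the index month, the raw prevalence
  increment ``values[0] - values[-1]`` in percent per month;
* ``irr_index`` — ratio of the exposed group's index-month IR to the
  control group's (undefined, reported "*", when the control IR is zero);
* ``ir_pre_annual`` / ``ir_post_annual`` / ``ird_annual`` — annualized
  incidence rates from the segmented-regression slopes: 12*b1, 12*(b1+b3),
  and their difference 12*b3 (percent per year).

IR/IRR come from raw month-0 increments; IRD comes from fitted slopes; the
fitted index-month level change (b2) and a raw slope-difference IRD are
cross-exported for comparison.  Fit errors and undefined ratios surface as
"*" cells in formatted tables and as distinct status codes in metrics.csv.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .its import ITSFit
from .trajectory import PrevalenceSeries

__all__ = [
    "MetricSet",
    "incidence_rate_at_index",
    "incidence_rate_ratio",
    "annual_rates",
    "compute_metrics",
    "rank_and_select",
    "make_report",
]

RANK_METRICS = ("prevalence_pre", "ir_index", "irr_index", "ird_annual")


@dataclass(frozen=True)
class MetricSet:
    condition_id: str
    group: str
    prevalence_pre: float
    ir_index: float
    irr_index: float | None
    ir_pre_annual: float | None
    ir_post_annual: float | None
    ird_annual: float | None
    ir_index_fitted: float | None
    ird_annual_raw: float
    fit_status: str


def incidence_rate_at_index(prev: PrevalenceSeries) -> float:
    """Raw index-month incidence: prevalence at offset 0 minus offset -1."""
    return prev.value_at(0) - prev.value_at(-1)


def incidence_rate_ratio(ir_exposed: float, ir_control: float) -> float | None:
    """Exposed/control index-month IR ratio; None (printed "*") when the
    control rate is zero."""
    if ir_exposed < 0 or ir_control < 0:
        raise ValueError("incidence rates must be non-negative")
    if ir_control == 0:
        return None
    return ir_exposed / ir_control


def annual_rates(fit: ITSFit) -> tuple[float, float, float]:
    """(pre, post, difference) annual incidence rates from fitted slopes."""
    if fit.status != "ok":
        raise ValueError("annual rates undefined for a fit_error fit")
    pre = 12.0 * fit.b1
    post = 12.0 * (fit.b1 + fit.b3)
    return pre, post, post - pre


def _raw_ird(prev: PrevalenceSeries) -> float:
    """Model-free IRD: 12 x (mean post-index increment - mean pre-index
    increment), exported alongside the fitted value."""
    inc = np.diff(prev.values)
    offs = prev.offsets[1:]
    pre = inc[offs < 0]
    post = inc[offs >= 0]
    return 12.0 * (float(post.mean()) - float(pre.mean()))


def compute_metrics(
    series_list: list[PrevalenceSeries],
    fits: dict[tuple[str, str], ITSFit],
    control_group: str = "control",
) -> pd.DataFrame:
    """One MetricSet row per condition x group.

    ``fits`` maps (condition_id, group) to the segmented-regression fit of
    that series.  IRRs compare each non-control group with the control
    series of the same condition.
    """
    by_key = {(s.condition_id, s.group): s for s in series_list}
    control_ir = {
        cond: incidence_rate_at_index(s)
        for (cond, grp), s in by_key.items()
        if grp == control_group
    }
    rows = []
    for (cond, grp), s in by_key.items():
        ir = incidence_rate_at_index(s)
        irr = None
        if grp != control_group and cond in control_ir:
            irr = incidence_rate_ratio(ir, control_ir[cond])
        fit = fits.get((cond, grp))
        status = fit.status if fit is not None else "fit_error"
        if fit is not None and fit.status == "ok":
            pre, post, ird = annual_rates(fit)
            b2 = fit.b2
        else:
            pre = post = ird = b2 = None
        rows.append(
            MetricSet(cond, grp, s.value_at(-1), ir, irr, pre, post, ird,
                      b2, _raw_ird(s), status)
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    return df.sort_values(["condition_id", "group"], kind="stable").reset_index(
        drop=True
    )


def rank_and_select(
    metrics: pd.DataFrame, k: int = 10
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Top-k condition rankings for the four headline metrics, plus the
    union set with per-metric membership flags.

    ``metrics`` must hold one row per condition (a single exposed group).
    Undefined IRRs are excluded from the IRR ranking.  Ties break
    deterministically by condition label.  Returns (rankings, union table
    ordered by descending prevalence).
    """
    if metrics["condition_id"].duplicated().any():
        raise ValueError("rank_and_select expects one row per condition")
    n = len(metrics)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available conditions")

    rankings: dict[str, list[str]] = {}
    for metric in RANK_METRICS:
        sub = metrics[["condition_id", metric]].dropna(subset=[metric])
        sub = sub.sort_values(
            [metric, "condition_id"], ascending=[False, True], kind="stable"
        )
        rankings[metric] = list(sub["condition_id"].head(k))

    union = sorted(set().union(*rankings.values()))
    flags = pd.DataFrame({"condition_id": union})
    for metric in RANK_METRICS:
        flags[f"in_top{k}_{metric}"] = flags["condition_id"].isin(
            set(rankings[metric])
        )
    prev = metrics.set_index("condition_id")["prevalence_pre"]
    flags["prevalence_pre"] = flags["condition_id"].map(prev)
    flags = flags.sort_values(
        ["prevalence_pre", "condition_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return rankings, flags


# -- formatting -----------------------------------------------------------

def _fmt_value(v: float | None) -> str:
    """Printed precision: one decimal at magnitude >= 1, two below."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "*"
    return f"{v:.1f}" if abs(v) >= 1 else f"{v:.2f}"


def _fmt_irr(v: float | None) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "*"
    return f"{v:.0f}" if v >= 10 else f"{v:.1f}"


def make_report(
    metrics: pd.DataFrame,
    fits: dict[tuple[str, str], ITSFit],
    series_list: list[PrevalenceSeries],
    out_dir: str | Path,
    table_group: str = "all_tbi",
    k: int = 10,
    plots: bool = False,
) -> dict[str, Path]:
    """Write metrics.csv, fits.csv and the ranked summary table.

    ``table3.csv`` lists the union of the four top-k condition sets for
    ``table_group``, ordered by descending pre-index prevalence, with "*"
    for undefined ratios and fit errors.  Optional plots: per-condition
    trajectory panels and top-k bar charts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    m = metrics.copy()
    paths["metrics"] = out / "metrics.csv"
    m.to_csv(paths["metrics"], index=False, float_format="%.10g")

    fit_rows = []
    for (cond, grp), f in sorted(fits.items()):
        fit_rows.append(
            {
                "condition_id": cond, "group": grp,
                "b0": f.b0, "b1": f.b1, "b2": f.b2, "b3": f.b3,
                "se_b0": f.stderr[0], "se_b1": f.stderr[1],
                "se_b2": f.stderr[2], "se_b3": f.stderr[3],
                "p_b0": f.pvalues[0], "p_b1": f.pvalues[1],
                "p_b2": f.pvalues[2], "p_b3": f.pvalues[3],
                "resid_sd": f.resid_sd, "status": f.status,
            }
        )
    paths["fits"] = out / "fits.csv"
    pd.DataFrame(fit_rows).to_csv(paths["fits"], index=False, float_format="%.10g")

    grp_metrics = metrics[metrics["group"] == table_group].reset_index(drop=True)
    if len(grp_metrics) >= k:
        _, flags = rank_and_select(grp_metrics, k=k)
        lookup = grp_metrics.set_index("condition_id")
        table = pd.DataFrame(
            {
                "condition": flags["condition_id"],
                "prevalence_pre_pct": [
                    _fmt_value(lookup.at[c, "prevalence_pre"])
                    for c in flags["condition_id"]
                ],
                "ir_pct_per_month": [
                    _fmt_value(lookup.at[c, "ir_index"])
                    for c in flags["condition_id"]
                ],
                "irr": [
                    _fmt_irr(lookup.at[c, "irr_index"])
                    for c in flags["condition_id"]
                ],
                "ird_pct_per_year": [
                    _fmt_value(lookup.at[c, "ird_annual"])
                    for c in flags["condition_id"]
                ],
            }
        )
        paths["table3"] = out / "table3.csv"
        table.to_csv(paths["table3"], index=False)
        paths["union"] = out / "top10_union.csv"
        flags.to_csv(paths["union"], index=False)

    if plots:
        paths.update(_make_plots(series_list, metrics, fits, out, table_group, k))
    return paths


def _make_plots(series_list, metrics, fits, out, table_group, k):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .its import predict

    paths = {}
    by_cond: dict[str, list[PrevalenceSeries]] = {}
    for s in series_list:
        by_cond.setdefault(s.condition_id, []).append(s)

    fig_dir = out / "figures"
    fig_dir.mkdir(exist_ok=True)
    for cond, group_series in sorted(by_cond.items()):
        fig, ax = plt.subplots(figsize=(6, 4))
        for s in group_series:
            ax.plot(s.offsets / 12.0, s.values, label=s.group)
            fit = fits.get((cond, s.group))
            if fit is not None and fit.status == "ok":
                ax.plot(
                    s.offsets / 12.0, predict(fit, s.offsets),
                    linestyle="--", linewidth=0.8, color="gray",
                )
        ax.set_xlabel("years from index")
        ax.set_ylabel("prevalence (%)")
        ax.set_title(cond)
        ax.legend(fontsize=7)
        p = fig_dir / f"trajectory_{cond}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths[f"trajectory_{cond}"] = p

    grp = metrics[metrics["group"] == table_group]
    if len(grp) >= k:
        rankings, _ = rank_and_select(grp.reset_index(drop=True), k=k)
        lookup = grp.set_index("condition_id")
        fig, axes = plt.subplots(2, 2, figsize=(11, 8))
        for ax, metric in zip(axes.ravel(), rankings):
            conds = rankings[metric]
            vals = [lookup.at[c, metric] for c in conds]
            ax.barh(range(len(conds))[::-1], vals)
            ax.set_yticks(range(len(conds))[::-1], conds, fontsize=7)
            ax.set_title(metric)
        fig.tight_layout()
        p = fig_dir / f"top{k}_bars.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths["top_bars"] = p
    return paths
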