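"""Threshold sweeps and privacy-utility trade-off curves.

For each scenario and each risk threshold on a grid, the cohort is
anonymized, empirical residual risks are measured on the released table, and
both utility families are computed: general-purpose information loss
(granularity, nonuniform entropy) and use-case-specific reproducibility
(overall 95% CI overlap of the analysis battery). Privacy columns are
reported as 1 - risk for plotting, giving a spectrum from 1 - maximum PR
through 1 - average PR (the marketer risk) to 1 - minimum PR.

Two threshold families exist: scaling the prosecutor-risk threshold alone
("pr"), and fixing PR at 50% while scaling the marketer-risk threshold
("pr_mr", the strict-average-risk family). Four privacy levels are
highlighted from moderate to very strict: 50%PR+9.09%MR, 50%PR+3.03%MR,
9.09%PR and 3.03%PR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .anonymizer import LatticeEvaluator
from .cohort import CohortTable
from .reproducibility import (AnalysisSpec, compare, default_battery,
                              run_analysis)
from .risk import group_size_for_threshold
from .scenarios import ScenarioConfig
from .utility import nonuniform_entropy

#: default grid: thresholds from 1.00 down to 0.02, canonicalized to group
#: sizes at evaluation time
DEFAULT_GRID = tuple(np.round(np.linspace(1.0, 0.02, 100), 4))

#: highlighted privacy levels, moderate to very strict
HIGHLIGHTS = (
    ("50% PR+9.09% MR", 0.5, 1 / 11),
    ("50% PR+3.03% MR", 0.5, 1 / 33),
    ("9.09% PR", 1 / 11, None),
    ("3.03% PR", 1 / 33, None),
)


def _threshold_label(pr: float, mr: float | None) -> str:
    def pct(t: float) -> str:
        s = f"{100 / group_size_for_threshold(t):.2f}".rstrip("0").rstrip(".")
        return f"{s}%"

    return f"{pct(pr)} PR" + (f"+{pct(mr)} MR" if mr is not None else "")


@dataclass
class SweepContext:
    """Per-scenario caches reused across the whole threshold grid."""

    scenario: ScenarioConfig
    evaluator: LatticeEvaluator
    orig_cells: list
    battery: list[AnalysisSpec]


def _make_context(cohort: CohortTable, scenario: ScenarioConfig,
                  battery: Sequence[AnalysisSpec] | None) -> SweepContext:
    battery = list(battery) if battery is not None else default_battery()
    evaluator = LatticeEvaluator(cohort, scenario.qis, scenario.hierarchies)
    orig_cells = [c for spec in battery
                  for c in run_analysis(cohort, spec)]
    return SweepContext(scenario=scenario, evaluator=evaluator,
                        orig_cells=orig_cells, battery=battery)


def _evaluate_threshold(ctx: SweepContext, pr: float, mr: float | None,
                        family: str) -> dict:
    model = ctx.scenario.model(pr, mr)
    ev = ctx.evaluator.search(model)
    result = ctx.evaluator.materialize(ev, model)
    kept = result.kept_index
    scheme = result.scheme.as_dict()
    entropy = nonuniform_entropy(ctx.evaluator.table, ctx.scenario.hierarchies,
                                 ctx.scenario.qis, scheme, kept)
    anon_cells = [c for spec in ctx.battery if spec.affected
                  for c in run_analysis(result.table, spec)]
    cio = compare(ctx.orig_cells, anon_cells, ctx.battery)
    row = {
        "scenario": ctx.scenario.name,
        "family": family,
        "threshold_label": _threshold_label(pr, mr),
        "pr_threshold": pr,
        "mr_threshold": mr if mr is not None else np.nan,
        "k": model.k,
        "feasible": result.feasible,
        "scheme": "/".join(f"{v}:{l}" for v, l in scheme.items()),
        "n_suppressed": result.n_suppressed,
        "granularity_pct": result.granularity_pct,
        "entropy_pct": entropy,
        "overall_cio_pct": cio.overall,
    }
    if result.risk is not None:
        row.update({
            "pr_max": result.risk.pr_max,
            "pr_avg": result.risk.pr_avg,
            "pr_min": result.risk.pr_min,
            "privacy_max_pr": 1 - result.risk.pr_max,
            "privacy_avg_pr": 1 - result.risk.pr_avg,
            "privacy_min_pr": 1 - result.risk.pr_min,
        })
    else:
        row.update({k: np.nan for k in (
            "pr_max", "pr_avg", "pr_min", "privacy_max_pr",
            "privacy_avg_pr", "privacy_min_pr")})
    for spec_id, pct in cio.per_analysis.items():
        row[f"cio_{spec_id}"] = pct
    return row


def sweep(cohort: CohortTable,
          scenarios: Iterable[ScenarioConfig],
          grid: Sequence[float] = DEFAULT_GRID,
          family: str = "pr",
          battery: Sequence[AnalysisSpec] | None = None,
          include_highlights: bool = True) -> pd.DataFrame:
    """One row per (scenario, threshold): risks, suppression, utilities.

    ``family="pr"`` scales the PR threshold over ``grid``; ``family="pr_mr"``
    fixes PR at 0.5 and scales the MR threshold. The four highlighted
    privacy levels are appended (tagged ``highlight``) when not already on
    the grid.
    """
    if family not in ("pr", "pr_mr"):
        raise ValueError("family must be 'pr' or 'pr_mr'")
    rows = []
    for scenario in scenarios:
        ctx = _make_context(cohort, scenario, battery)
        seen = set()
        for t in grid:
            pr, mr = (t, None) if family == "pr" else (0.5, min(t, 0.5))
            row = _evaluate_threshold(ctx, pr, mr, family)
            row["highlight"] = ""
            rows.append(row)
            seen.add((row["k"],
                      group_size_for_threshold(mr) if mr else None))
        if include_highlights:
            for label, pr, mr in HIGHLIGHTS:
                fam = "pr_mr" if mr is not None else "pr"
                row = _evaluate_threshold(ctx, pr, mr, fam)
                row["highlight"] = label
                rows.append(row)
    return pd.DataFrame(rows)


def curve_export(rows: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Plot-ready privacy-utility curve tables.

    One table per (scenario, utility metric, privacy axis), sorted by
    privacy ascending, with the synthetic anchor points (0,100) and (100,0)
    appended and flagged ``measured=False`` — they close the curves visually
    but were not produced by any anonymization run.
    """
    if len(rows) == 0:
        raise ValueError("no sweep rows to export")
    metrics = ("granularity_pct", "entropy_pct", "overall_cio_pct")
    axes = ("privacy_max_pr", "privacy_avg_pr", "privacy_min_pr")
    out: dict[str, pd.DataFrame] = {}
    for scenario, sub in rows.groupby("scenario"):
        feas = sub[sub["feasible"].astype(bool)]
        for metric in metrics:
            for axis in axes:
                pts = pd.DataFrame({
                    "privacy_pct": 100 * feas[axis],
                    "utility_pct": feas[metric],
                    "threshold_label": feas["threshold_label"],
                    "measured": True,
                }).dropna(subset=["privacy_pct"])
                anchors = pd.DataFrame({
                    "privacy_pct": [0.0, 100.0],
                    "utility_pct": [100.0, 0.0],
                    "threshold_label": ["anchor", "anchor"],
                    "measured": [False, False],
                })
                tbl = pd.concat([pts, anchors], ignore_index=True)
                tbl = tbl.sort_values("privacy_pct",
                                      kind="stable").reset_index(drop=True)
                out[f"{scenario}__{metric}__{axis}"] = tbl
    return out
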