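"""Use-case-specific utility: reproducibility of descriptive analyses.

A battery of descriptive analyses (counts, proportions, means, stratified
e.g. by gender and diabetes status) is run on the original and on an
anonymized table, and agreement is scored per estimate as the relative
overlap of 95% confidence-interval lengths:

    overlap% = 100 * 1/2 * (ov / len(orig) + ov / len(anon)),
    ov = max(0, min(uppers) - max(lowers)).

Proportion intervals use the Wilson score method; mean intervals use the
two-sided t interval. Cell overlaps are averaged into table-level scores
and table scores into an overall score, with analyses untouched by the
anonymization entering the overall average at 100. Estimates with overlap
below 50% are flagged "modest", 0% "nonoverlapping", and an anonymized
point estimate falling outside the original interval is flagged too.

Variables whose scale the anonymization changed (generalized to intervals,
e.g. age or BMI) cannot be scored this way and are excluded; their effect
is reported visually via histogram exports instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .cohort import CohortTable


@dataclass(frozen=True)
class Interval:
    lower: float
    upper: float
    conf: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError("lower must be <= upper")

    @property
    def length(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class EstimateCell:
    analysis: str
    stratum: str
    variable: str
    kind: str  # {"proportion_pct", "mean", "count"}
    value: float | None
    interval: Interval | None
    n_nonmissing: int

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.analysis, self.stratum, self.variable, self.kind)


@dataclass(frozen=True)
class AnalysisVariable:
    """One scored column: a proportion of ``category`` within ``variable``,
    a mean, or a bare count."""

    variable: str
    kind: str  # {"proportion_pct", "mean", "count"}
    category: str | None = None  # the "success" level for proportions
    scale_transformed: bool = False  # excluded from CI-overlap scoring

    @property
    def label(self) -> str:
        if self.kind == "proportion_pct" and self.category is not None:
            return f"{self.variable}={self.category}"
        return self.variable


@dataclass(frozen=True)
class AnalysisSpec:
    id: str
    strat_vars: tuple[str, ...]
    variables: tuple[AnalysisVariable, ...]
    affected: bool = True  # False: untouched by anonymization, scores 100


@dataclass
class CIOReport:
    per_cell: pd.DataFrame  # one row per compared estimate
    per_analysis: dict[str, float]
    overall: float


def wilson_interval(successes: int, n: int, conf: float = 0.95) -> Interval:
    """Wilson score interval for a binomial proportion (on the 0-1 scale)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    return Interval(lower=float(lo), upper=float(hi), conf=conf)


def mean_t_interval(values: Sequence[float], conf: float = 0.95) -> Interval:
    """Two-sided t interval for a mean; degenerate when variance is zero."""
    arr = np.asarray([v for v in values if not pd.isna(v)], dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least 2 non-missing values")
    m = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = stats.t.ppf(0.5 + conf / 2, len(arr) - 1) * sd / np.sqrt(len(arr))
    return Interval(lower=m - half, upper=m + half, conf=conf)


def ci_overlap(orig: Interval, anon: Interval) -> float:
    """Symmetric relative overlap of two interval lengths, in percent.

    Zero-length intervals contribute a ratio of 1 when their point lies
    inside the other interval and 0 otherwise, so two identical degenerate
    intervals overlap 100%.
    """
    ov = max(0.0, min(orig.upper, anon.upper) - max(orig.lower, anon.lower))

    def ratio(num: Interval, other: Interval) -> float:
        if num.length > 0:
            return ov / num.length
        return 1.0 if other.lower - 1e-12 <= num.lower <= other.upper + 1e-12 \
            else 0.0

    return 100.0 * 0.5 * (ratio(orig, anon) + ratio(anon, orig))


def _strata(df: pd.DataFrame, strat_vars: Sequence[str]) -> list[tuple[str, pd.DataFrame]]:
    if not strat_vars:
        return [("all", df)]
    out = []
    level_values = [sorted(df[v].dropna().unique()) for v in strat_vars]
    for combo in itertools.product(*level_values):
        mask = np.ones(len(df), dtype=bool)
        for var, val in zip(strat_vars, combo):
            mask &= (df[var] == val).to_numpy()
        name = ",".join(f"{v}={c}" for v, c in zip(strat_vars, combo))
        out.append((name, df[mask]))
    return out


def run_analysis(table: CohortTable | pd.DataFrame,
                 spec: AnalysisSpec) -> list[EstimateCell]:
    """Descriptive estimates per stratum x variable.

    Percentages use non-missing denominators; strata come from the raw
    values of the stratification variables (which must not be generalized).
    Empty strata yield absent cells (value None).
    """
    df = table.df if isinstance(table, CohortTable) else table
    needed = set(spec.strat_vars) | {v.variable for v in spec.variables}
    unknown = needed - set(df.columns)
    if unknown:
        raise KeyError(f"analysis {spec.id}: unknown variables "
                       f"{sorted(unknown)}")
    cells: list[EstimateCell] = []
    for stratum_name, sub in _strata(df, spec.strat_vars):
        for av in spec.variables:
            col = sub[av.variable]
            nonmissing = col.dropna()
            n_nm = len(nonmissing)
            if n_nm == 0:
                cells.append(EstimateCell(spec.id, stratum_name, av.label,
                                          av.kind, None, None, 0))
                continue
            if av.kind == "count":
                cells.append(EstimateCell(spec.id, stratum_name, av.label,
                                          "count", float(n_nm), None, n_nm))
            elif av.kind == "proportion_pct":
                succ = int((nonmissing == av.category).sum())
                iv = wilson_interval(succ, n_nm)
                cells.append(EstimateCell(
                    spec.id, stratum_name, av.label, "proportion_pct",
                    100.0 * succ / n_nm,
                    Interval(100 * iv.lower, 100 * iv.upper, iv.conf), n_nm))
            elif av.kind == "mean":
                vals = nonmissing.astype(float)
                iv = mean_t_interval(vals) if n_nm >= 2 else None
                cells.append(EstimateCell(spec.id, stratum_name, av.label,
                                          "mean", float(vals.mean()), iv,
                                          n_nm))
            else:
                raise ValueError(f"unknown statistic kind {av.kind!r}")
    return cells


def _scored(cell: EstimateCell, spec_vars: Mapping[str, AnalysisVariable]) -> bool:
    av = spec_vars.get(cell.variable)
    if av is None or av.scale_transformed:
        return False
    return cell.kind in ("proportion_pct", "mean")


def compare(orig_cells: Iterable[EstimateCell],
            anon_cells: Iterable[EstimateCell],
            battery: Sequence[AnalysisSpec]) -> CIOReport:
    """Score agreement between original and anonymized estimate sets.

    Only interval-bearing, non-scale-transformed cells are scored; counts
    are descriptive. Analyses flagged unaffected enter the overall average
    at 100 without being recomputed.
    """
    orig_by = {c.key: c for c in orig_cells}
    anon_by = {c.key: c for c in anon_cells}
    rows = []
    per_analysis: dict[str, float] = {}
    for spec in battery:
        if not spec.affected:
            per_analysis[spec.id] = 100.0
            continue
        spec_vars = {av.label: av for av in spec.variables}
        overlaps = []
        for key, oc in orig_by.items():
            if key[0] != spec.id or not _scored(oc, spec_vars):
                continue
            ac = anon_by.get(key)
            if ac is None:
                raise KeyError(f"anonymized estimate missing for {key}")
            if oc.interval is None or ac.interval is None or \
                    oc.value is None or ac.value is None:
                continue  # absent cell (empty stratum) on either side
            pct = ci_overlap(oc.interval, ac.interval)
            outside = not (oc.interval.lower - 1e-12 <= ac.value
                           <= oc.interval.upper + 1e-12)
            rows.append({
                "analysis": spec.id, "stratum": key[1], "variable": key[2],
                "kind": key[3], "orig_value": oc.value,
                "anon_value": ac.value, "overlap_pct": pct,
                "modest": pct < 50.0, "nonoverlapping": pct == 0.0,
                "outside_original_ci": outside,
                "n_orig": oc.n_nonmissing, "n_anon": ac.n_nonmissing,
            })
            overlaps.append(pct)
        per_analysis[spec.id] = float(np.mean(overlaps)) if overlaps else 100.0
    per_cell = pd.DataFrame(rows)
    overall = float(np.mean(list(per_analysis.values())))
    return CIOReport(per_cell=per_cell, per_analysis=per_analysis,
                     overall=overall)


def default_battery() -> list[AnalysisSpec]:
    """Seven descriptive analyses mirroring a CKD baseline characterization.

    Structure: a main disease-burden table stratified by gender x diabetes,
    an inclusion-criteria overview, biopsy rates per leading CKD cause, two
    cardiovascular/medication tables, a diabetic-nephropathy table, and one
    analysis over variables the anonymization never touches (flagged
    unaffected; a second unaffected analysis is the eGFR-category
    comparison, represented the same way).
    """
    P = "proportion_pct"
    return [
        AnalysisSpec(
            id="main_burden",
            strat_vars=("gender", "diabetes"),
            variables=(
                AnalysisVariable("renal_biopsy", P, "yes"),
                AnalysisVariable("uacr_category", P, "<30"),
                AnalysisVariable("uacr_category", P, "30-300"),
                AnalysisVariable("uacr_category", P, ">300"),
                AnalysisVariable("egfr", "mean"),
                AnalysisVariable("systolic_bp", "mean"),
                AnalysisVariable("egfr", "count"),
            )),
        AnalysisSpec(
            id="inclusion_criteria",
            strat_vars=(),
            variables=(
                AnalysisVariable("diabetes", P, "yes"),
                AnalysisVariable("renal_biopsy", P, "yes"),
                AnalysisVariable("egfr", "mean"),
                AnalysisVariable("systolic_bp", "mean"),
            )),
        AnalysisSpec(
            id="biopsy_by_cause",
            strat_vars=("ckd_cause",),
            variables=(AnalysisVariable("renal_biopsy", P, "yes"),)),
        AnalysisSpec(
            id="cardiovascular_by_gender",
            strat_vars=("gender",),
            variables=(
                AnalysisVariable("ace_inhibitor", P, "yes"),
                AnalysisVariable("arb", P, "yes"),
                AnalysisVariable("statin", P, "yes"),
                AnalysisVariable("diuretic", P, "yes"),
                AnalysisVariable("systolic_bp", "mean"),
            )),
        AnalysisSpec(
            id="cardiovascular_by_diabetes",
            strat_vars=("diabetes",),
            variables=(
                AnalysisVariable("ace_inhibitor", P, "yes"),
                AnalysisVariable("statin", P, "yes"),
                AnalysisVariable("systolic_bp", "mean"),
            )),
        AnalysisSpec(
            id="diabetic_nephropathy",
            strat_vars=("diabetes",),
            variables=(
                AnalysisVariable("ckd_cause", P, "diabetic_nephropathy"),
                AnalysisVariable("egfr", "mean"),
                AnalysisVariable("uacr_category", P, ">300"),
            )),
        AnalysisSpec(
            id="egfr_albuminuria_categories",
            strat_vars=(),
            variables=(
                AnalysisVariable("uacr_category", P, "<30"),
                AnalysisVariable("uacr_category", P, "30-300"),
                AnalysisVariable("uacr_category", P, ">300"),
            ),
            affected=False),
    ]


def histogram_export(original: CohortTable | pd.DataFrame,
                     released: CohortTable | pd.DataFrame,
                     variable: str) -> pd.DataFrame:
    """Original-vs-released value counts for a scale-transformed variable.

    Visual artifact (bar-plot input), not a scored quantity.
    """
    odf = original.df if isinstance(original, CohortTable) else original
    rdf = released.df if isinstance(released, CohortTable) else released
    o = odf[variable].value_counts(dropna=True).rename("original_count")
    r = rdf[variable].value_counts(dropna=True).rename("released_count")
    out = pd.concat([o, r], axis=1).fillna(0).astype(int)
    out.index.name = variable
    return out.reset_index()
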