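"""General-purpose information-loss metrics.

Two standard loss models are scored over the quasi-identifier columns of a
released table, each normalized so that 100% means no information modified
and 0% means all information removed (every record suppressed):

* **granularity** (cell level): a kept cell generalized to a label covering
  m of the variable's M distinct original values loses (m-1)/(M-1); a
  suppressed record's cells lose 1. The metric is 100 x (1 - mean loss over
  all quasi-identifier cells of all original records).

* **nonuniform entropy** (variable level): a kept cell with original value v
  generalized to label g loses -log2(f0(v)/f1(g)), where f0 and f1 are the
  numbers of original records carrying v and mapped into g respectively; a
  suppressed cell loses -log2(f0(v)/n). Each variable's summed loss is
  normalized by its all-suppressed maximum and the per-variable percentages
  are averaged.

Domains are empirical (distinct values present in the original data) and all
frequencies come from the original table, so the metrics are comparable
across privacy thresholds. Both metrics are anti-monotone in every
hierarchy level. Restricting to quasi-identifier columns is deliberate:
untouched columns would otherwise dilute the loss toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .hierarchy import Hierarchy

_MISSING = "__missing__"


@dataclass(frozen=True)
class UtilityReport:
    granularity_pct: float
    entropy_pct: float
    granularity_by_variable: dict[str, float]
    entropy_by_variable: dict[str, float]


def _filled_column(df: pd.DataFrame, var: str) -> np.ndarray:
    col = df[var].astype(object)
    return col.where(pd.notna(col), _MISSING).to_numpy()


def granularity_cell_losses(original_col: np.ndarray, h: Hierarchy,
                            level: int) -> np.ndarray:
    """Per-record granularity loss for one variable at one level.

    Missing cells carry no information and lose 0 while kept.
    """
    values = pd.Series(original_col)
    distinct = [v for v in values.unique() if v != _MISSING]
    M = len(distinct)
    if level == 0 or M <= 1:
        return np.zeros(len(values))
    labels = {v: h.generalize(v, level) for v in distinct}
    m_per_label: dict = {}
    for v, lab in labels.items():
        m_per_label[lab] = m_per_label.get(lab, 0) + 1
    loss_per_value = {v: (m_per_label[labels[v]] - 1) / (M - 1)
                      for v in distinct}
    loss_per_value[_MISSING] = 0.0
    return values.map(loss_per_value).to_numpy(dtype=float)


def entropy_cell_losses(original_col: np.ndarray, h: Hierarchy,
                        level: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-record entropy losses: (kept-at-level loss, suppressed loss).

    The suppressed loss -log2(f0(v)/n) is also the per-cell maximum used for
    normalization.
    """
    values = pd.Series(original_col)
    n = len(values)
    f0 = values.map(values.value_counts()).to_numpy(dtype=float)
    max_loss = np.log2(n) - np.log2(f0)
    if level == 0:
        return np.zeros(n), max_loss
    distinct = [v for v in values.unique() if v != _MISSING]
    labels = {v: h.generalize(v, level) for v in distinct}
    labels[_MISSING] = _MISSING
    lab_col = values.map(labels)
    f1 = lab_col.map(lab_col.value_counts()).to_numpy(dtype=float)
    return np.log2(f1) - np.log2(f0), max_loss


def granularity(original: CohortTable | pd.DataFrame,
                hierarchies: Mapping[str, Hierarchy],
                qis: Sequence[str],
                scheme: Mapping[str, int],
                kept: Sequence[int] | np.ndarray) -> float:
    """Granularity percentage of a release defined by ``scheme`` + ``kept``."""
    df = original.df if isinstance(original, CohortTable) else original
    n = len(df)
    kept_mask = np.zeros(n, dtype=bool)
    kept_mask[np.asarray(list(kept), dtype=int)] = True
    total = 0.0
    for var in qis:
        losses = granularity_cell_losses(_filled_column(df, var),
                                         hierarchies[var], scheme[var])
        total += losses[kept_mask].sum() + float((~kept_mask).sum())
    return 100.0 * (1.0 - total / (n * len(qis)))


def nonuniform_entropy(original: CohortTable | pd.DataFrame,
                       hierarchies: Mapping[str, Hierarchy],
                       qis: Sequence[str],
                       scheme: Mapping[str, int],
                       kept: Sequence[int] | np.ndarray) -> float:
    """Nonuniform-entropy percentage (per-variable normalized, then averaged)."""
    df = original.df if isinstance(original, CohortTable) else original
    n = len(df)
    kept_mask = np.zeros(n, dtype=bool)
    kept_mask[np.asarray(list(kept), dtype=int)] = True
    pcts = []
    for var in qis:
        kept_loss, max_loss = entropy_cell_losses(
            _filled_column(df, var), hierarchies[var], scheme[var])
        maximum = max_loss.sum()
        if maximum <= 0.0:
            pcts.append(100.0)
            continue
        total = kept_loss[kept_mask].sum() + max_loss[~kept_mask].sum()
        pcts.append(100.0 * (1.0 - total / maximum))
    return float(np.mean(pcts))


def utility_report(original: CohortTable | pd.DataFrame,
                   hierarchies: Mapping[str, Hierarchy],
                   qis: Sequence[str],
                   scheme: Mapping[str, int],
                   kept: Sequence[int] | np.ndarray) -> UtilityReport:
    """Both metrics plus per-variable breakdowns for one release."""
    df = original.df if isinstance(original, CohortTable) else original
    n = len(df)
    kept_mask = np.zeros(n, dtype=bool)
    kept_mask[np.asarray(list(kept), dtype=int)] = True
    gran_by, ent_by = {}, {}
    for var in qis:
        col = _filled_column(df, var)
        g_losses = granularity_cell_losses(col, hierarchies[var], scheme[var])
        g_total = g_losses[kept_mask].sum() + float((~kept_mask).sum())
        gran_by[var] = 100.0 * (1.0 - g_total / n)
        kept_loss, max_loss = entropy_cell_losses(col, hierarchies[var],
                                                  scheme[var])
        maximum = max_loss.sum()
        if maximum <= 0.0:
            ent_by[var] = 100.0
        else:
            total = kept_loss[kept_mask].sum() + max_loss[~kept_mask].sum()
            ent_by[var] = 100.0 * (1.0 - total / maximum)
    return UtilityReport(
        granularity_pct=float(np.mean(list(gran_by.values()))),
        entropy_pct=float(np.mean(list(ent_by.values()))),
        granularity_by_variable=gran_by,
        entropy_by_variable=ent_by,
    )
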