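"""Reidentification risk under the prosecutor and marketer models.

For a released table, records are grouped into equivalence classes by exact
equality of their (possibly generalized) quasi-identifier tuples. With u(r)
the size of record r's class, the record-level reidentification risk is
1/u(r). The prosecutor risk (PR) of the data set is the maximum of this
distribution — the success probability against a targeted record known to be
in the data — and the marketer risk (MR) is its average, which equals the
number of classes divided by the number of records. Enforcing PR <= 1/k is
k-anonymity; additionally bounding MR is the strict-average-risk model.

Printed thresholds like 9.09% or 3.03% are rounded reciprocals; they are
canonicalized to exact group sizes (1/11, 1/33) via
:func:`group_size_for_threshold`, so a class of exactly k records satisfies
the threshold. Suppressed records are excluded from all risk statistics:
they are not released, so only kept records carry residual risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable

_EPS = 1e-12
_MISSING_SENTINEL = "__missing__"  # missing qi values compare equal


@dataclass
class EquivalencePartition:
    """Equivalence classes over kept records; ``excluded`` are suppressed."""

    classes: list[np.ndarray]  # record-index arrays, partitioning kept rows
    excluded: frozenset[int]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(c) for c in self.classes], dtype=int)

    @property
    def n_kept(self) -> int:
        return int(self.sizes.sum()) if self.classes else 0


@dataclass(frozen=True)
class RiskSummary:
    pr_max: float
    pr_avg: float  # == marketer risk
    pr_min: float
    n_kept: int
    n_suppressed: int


@dataclass(frozen=True)
class PrivacyModel:
    """Thresholds the anonymizer must enforce on the released table."""

    pr_threshold: float
    mr_threshold: float | None = None
    suppression_limit: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.pr_threshold <= 1.0:
            raise ValueError("pr_threshold must be in (0, 1]")
        if self.mr_threshold is not None:
            if not 0.0 < self.mr_threshold <= 1.0:
                raise ValueError("mr_threshold must be in (0, 1]")
            if self.mr_threshold > self.pr_threshold + _EPS:
                raise ValueError("mr_threshold must not exceed pr_threshold")
        if not 0.0 <= self.suppression_limit <= 1.0:
            raise ValueError("suppression_limit must be in [0, 1]")

    @property
    def k(self) -> int:
        return group_size_for_threshold(self.pr_threshold)


def partition(table: CohortTable | pd.DataFrame, qis: Sequence[str],
              suppressed: frozenset[int] | set[int] = frozenset(),
              ) -> EquivalencePartition:
    """Group non-suppressed records by their exact quasi-identifier tuple."""
    df = table.df if isinstance(table, CohortTable) else table
    qis = list(qis)
    unknown = set(qis) - set(df.columns)
    if unknown:
        raise KeyError(f"unknown quasi-identifiers: {sorted(unknown)}")
    suppressed = frozenset(suppressed)
    kept = df.index[~df.index.isin(suppressed)]
    sub = df.loc[kept, qis].astype(object)
    sub = sub.where(pd.notna(sub), _MISSING_SENTINEL)
    groups = sub.groupby(qis, sort=False, observed=True).indices
    classes = [kept[np.sort(idx)].to_numpy() for idx in groups.values()]
    return EquivalencePartition(classes=classes, excluded=suppressed)


def risk_summary(p: EquivalencePartition) -> RiskSummary:
    """Empirical prosecutor/marketer risks of the kept records."""
    sizes = p.sizes
    if len(sizes) == 0:
        raise ValueError("empty partition has no risk distribution")
    n_kept = int(sizes.sum())
    return RiskSummary(
        pr_max=1.0 / sizes.min(),
        pr_avg=len(sizes) / n_kept,
        pr_min=1.0 / sizes.max(),
        n_kept=n_kept,
        n_suppressed=len(p.excluded),
    )


def group_size_for_threshold(t: float) -> int:
    """Largest k with 1/k >= t; the enforced constraint is u(r) >= k.

    Canonicalizes rounded percentage thresholds: 0.5 -> 2, 0.09 -> 11,
    0.03 -> 33, 1.0 -> 1.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return int(math.floor(1.0 / t + 1e-9))


def satisfies(model: PrivacyModel, s: RiskSummary,
              suppressed_fraction: float) -> bool:
    """True iff the summary meets all thresholds within the suppression budget."""
    if s.pr_max > 1.0 / model.k + _EPS:
        return False
    if model.mr_threshold is not None and s.pr_avg > model.mr_threshold + _EPS:
        return False
    return suppressed_fraction <= model.suppression_limit + _EPS
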