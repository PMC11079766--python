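"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and dicts,
independent of the vectorized code paths it verifies. Hierarchy objects are
used only to ask for a value's label (they define the transformation under
test, not the statistic being checked).
"""

from __future__ import annotations

import itertools
import math
from collections import Counter


def per_record_risks(rows: list[tuple]) -> list[float]:
    """1/u(r) for every record, by direct counting."""
    counts = Counter(rows)
    return [1.0 / counts[r] for r in rows]


def risk_triple(rows: list[tuple]) -> tuple[float, float, float]:
    """(max, average, min) of the per-record risk distribution."""
    risks = per_record_risks(rows)
    return max(risks), sum(risks) / len(risks), min(risks)


def generalize_rows(df, qis, hierarchies, levels) -> list[tuple]:
    out = []
    for _, rec in df.iterrows():
        tup = []
        for var, lev in zip(qis, levels):
            v = rec[var]
            tup.append(hierarchies[var].generalize(v, lev) if lev else v)
        out.append(tuple(tup))
    return out


def suppression_oracle(rows: list[tuple], k: int, mr: float | None,
                       limit: float) -> tuple[set, bool]:
    """Record indices to suppress under the k rule + marketer-risk repair.

    Classes are indexed in order of first appearance; repair removes whole
    classes smallest-first (ties: lower class index) while the budget allows.
    """
    n = len(rows)
    classes: dict[tuple, list[int]] = {}
    for i, r in enumerate(rows):
        classes.setdefault(r, []).append(i)
    class_list = list(classes.values())  # first-appearance order
    suppressed: set[int] = set()
    kept_classes = []
    for members in class_list:
        if len(members) < k:
            suppressed.update(members)
        else:
            kept_classes.append(members)
    if mr is not None:
        order = sorted(range(len(kept_classes)),
                       key=lambda i: (len(kept_classes[i]), i))
        removed = set()
        for i in order:
            n_kept = n - len(suppressed)
            n_classes = len(kept_classes) - len(removed)
            if n_kept <= 0 or n_classes <= 0:
                break
            if n_classes / n_kept <= mr + 1e-12:
                break
            s = len(kept_classes[i])
            if (len(suppressed) + s) / n > limit + 1e-12:
                break
            suppressed.update(kept_classes[i])
            removed.add(i)
        kept_classes = [c for i, c in enumerate(kept_classes)
                        if i not in removed]
    feasible = True
    if len(suppressed) / n > limit + 1e-12:
        feasible = False
    if kept_classes:
        sizes = [len(c) for c in kept_classes]
        if min(sizes) < k:
            feasible = False
        if mr is not None and len(sizes) / sum(sizes) > mr + 1e-12:
            feasible = False
    return suppressed, feasible


def granularity_oracle(df, qis, hierarchies, levels,
                       suppressed: set) -> float:
    """Cell-by-cell granularity percentage, fully looped."""
    n = len(df)
    total = 0.0
    for var, lev in zip(qis, levels):
        col = [v for v in df[var] if v == v]  # drop NaN
        distinct = sorted(set(col), key=str)
        M = len(distinct)
        label_of = {v: (hierarchies[var].generalize(v, lev) if lev else v)
                    for v in distinct}
        m_of = Counter(label_of.values())
        for i, v in enumerate(df[var]):
            if i in suppressed:
                total += 1.0
            elif v == v and M > 1:
                total += (m_of[label_of[v]] - 1) / (M - 1)
    return 100.0 * (1.0 - total / (n * len(qis)))


def search_oracle(df, qis, hierarchies, k_threshold: float,
                  mr: float | None, limit: float):
    """Exhaustive lattice search with the documented tie rule.

    Returns (levels, n_suppressed, granularity) of the optimum, or None if
    no node is feasible.
    """
    k = math.floor(1.0 / k_threshold + 1e-9)
    qis = sorted(qis)
    ranges = [range(hierarchies[v].max_level + 1) for v in qis]
    best = None
    best_key = None
    for levels in itertools.product(*ranges):
        rows = generalize_rows(df, qis, hierarchies, levels)
        suppressed, feasible = suppression_oracle(rows, k, mr, limit)
        if not feasible:
            continue
        gran = granularity_oracle(df, qis, hierarchies, levels, suppressed)
        key = (-round(gran, 9), sum(levels), levels)
        if best is None or key < best_key:
            best = (levels, len(suppressed), gran)
            best_key = key
    return best
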