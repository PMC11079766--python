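"""Generalization hierarchies.

A hierarchy is an ordered sequence of nested coarsenings of a variable's
domain. Level 0 is the identity (raw values); each higher level maps every
in-domain value to a label — an interval string ``"[a,b)"`` for continuous
variables or a named category group. Nestedness is structural: every class
at level l is wholly contained in exactly one class at level l+1, which is
what full-domain generalization relies on.

Interval hierarchies are anchored at the domain minimum with left-closed,
right-open intervals whose width grows by a constant grouping factor per
level; the final interval of a level is closed at the domain maximum and a
level that spans the whole domain is written ``"[min,max]"``. Dichotomous
variables are never generalized (suppression only), so their hierarchy is
the identity alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd


def _fmt(x: float) -> str:
    """Format a bound without a trailing '.0' so labels round-trip cleanly."""
    xf = float(x)
    return str(int(xf)) if xf == int(xf) else repr(xf)


def parse_interval_label(label: str) -> tuple[float, float, bool]:
    """Parse ``"[a,b)"`` / ``"[a,b]"`` back into (a, b, right_closed)."""
    if not label.startswith("[") or label[-1] not in ")]":
        raise ValueError(f"not an interval label: {label!r}")
    a, b = label[1:-1].split(",")
    return float(a), float(b), label[-1] == "]"


@dataclass(frozen=True)
class IntervalSpec:
    """Interval-hierarchy construction parameters for one variable."""

    min: float
    max: float
    base_width: float
    grouping_factor: int = 2

    def __post_init__(self) -> None:
        if self.min >= self.max:
            raise ValueError("min must be < max")
        if self.base_width <= 0:
            raise ValueError("base_width must be positive")
        if self.base_width >= self.max - self.min:
            raise ValueError("base_width covers the whole domain (degenerate)")
        if self.grouping_factor < 2:
            raise ValueError("grouping_factor must be >= 2")

    def width_at(self, level: int) -> float:
        return self.base_width * self.grouping_factor ** (level - 1)


@dataclass
class Hierarchy:
    """Ordered nested generalization levels for one variable.

    ``level_fns[l]`` maps a raw value to its level-l label; index 0 is the
    identity. Use :func:`generalize_value` or :meth:`generalize_array`.
    """

    variable: str
    level_fns: list[Callable] = field(repr=False)
    max_level: int = 0
    spec: IntervalSpec | None = None

    def generalize(self, value, level: int):
        if not 0 <= level <= self.max_level:
            raise ValueError(
                f"{self.variable}: level {level} outside [0, {self.max_level}]")
        return self.level_fns[level](value)

    def generalize_array(self, values: np.ndarray, level: int) -> np.ndarray:
        """Vectorized generalization; missing values stay missing."""
        if not 0 <= level <= self.max_level:
            raise ValueError(
                f"{self.variable}: level {level} outside [0, {self.max_level}]")
        if level == 0:
            return np.asarray(values, dtype=object)
        out = np.empty(len(values), dtype=object)
        fn = self.level_fns[level]
        for i, v in enumerate(values):
            if _is_missing(v):
                out[i] = v
            else:
                out[i] = fn(v)
        return out

    def lookup_table(self, values: Sequence) -> pd.DataFrame:
        """Materialize the hierarchy as one column per level for ``values``.

        Mirrors the flat hierarchy files common anonymization tools consume.
        """
        data = {"level_0": list(values)}
        for lev in range(1, self.max_level + 1):
            data[f"level_{lev}"] = [self.level_fns[lev](v) for v in values]
        return pd.DataFrame(data)


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def build_interval_hierarchy(spec: IntervalSpec,
                             variable: str = "",
                             cap: int | None = None) -> Hierarchy:
    """Interval hierarchy anchored at ``spec.min``.

    Level 1 partitions [min, max] into left-closed right-open intervals of
    ``base_width`` (last interval closed at max); each further level merges
    ``grouping_factor`` consecutive intervals. The natural top level is the
    first whose single interval covers the whole domain; ``cap`` (a level
    number) restricts generalization below that.
    """
    if cap is not None and cap < 1:
        raise ValueError("cap must be >= 1")
    span = spec.max - spec.min
    natural_top = 1
    while spec.width_at(natural_top) < span:
        natural_top += 1
    max_level = natural_top if cap is None else min(cap, natural_top)

    def make_fn(level: int) -> Callable:
        width = spec.width_at(level)
        n_intervals = int(np.ceil(span / width))

        def fn(value):
            v = float(value)
            if v < spec.min or v > spec.max:
                raise ValueError(
                    f"{variable or 'value'} {value} outside "
                    f"[{_fmt(spec.min)},{_fmt(spec.max)}]")
            idx = min(int((v - spec.min) // width), n_intervals - 1)
            a = spec.min + idx * width
            b = a + width
            if b >= spec.max:
                return f"[{_fmt(a)},{_fmt(spec.max)}]"
            return f"[{_fmt(a)},{_fmt(b)})"

        return fn

    fns: list[Callable] = [lambda v: v]
    fns += [make_fn(lev) for lev in range(1, max_level + 1)]
    return Hierarchy(variable=variable, level_fns=fns, max_level=max_level,
                     spec=spec)


def build_category_hierarchy(
    variable: str,
    level_maps: Sequence[Mapping | Callable],
) -> Hierarchy:
    """Category hierarchy from explicit per-level maps.

    ``level_maps[0]`` maps raw values to level-1 labels, ``level_maps[i]``
    maps level-i labels to level-(i+1) labels; entries may be dicts (checked
    for totality over the previous level's labels where enumerable) or
    callables (e.g. numeric banding). An empty ``level_maps`` yields the
    identity-only hierarchy used for dichotomous variables.
    """
    fns: list[Callable] = [lambda v: v]
    composed: Callable | None = None
    prev_labels: set | None = None
    for i, lm in enumerate(level_maps):
        if isinstance(lm, Mapping):
            if prev_labels is not None:
                missing = prev_labels - set(lm)
                if missing:
                    raise ValueError(
                        f"{variable}: level-{i + 1} map not total, missing "
                        f"{sorted(map(str, missing))}")
            this_map = dict(lm)
            prev = composed

            def step(v, _m=this_map, _prev=prev):
                u = _prev(v) if _prev is not None else v
                try:
                    return _m[u]
                except KeyError:
                    raise ValueError(
                        f"{variable}: value {v!r} not covered at level") from None

            composed = step
            prev_labels = set(this_map.values())
        else:
            prev = composed

            def step(v, _fn=lm, _prev=prev):
                return _fn(_prev(v) if _prev is not None else v)

            composed = step
            prev_labels = None
        fns.append(composed)
    return Hierarchy(variable=variable, level_fns=fns,
                     max_level=len(level_maps))


def identity_hierarchy(variable: str) -> Hierarchy:
    """Suppression-only variables: level 0 is the only level."""
    return build_category_hierarchy(variable, [])


def banded_map(cutpoints: Sequence[float], labels: Sequence[str]) -> Callable:
    """Map numbers into half-open bands: v < c0, c0 <= v < c1, ..., v >= c_last."""
    if len(labels) != len(cutpoints) + 1:
        raise ValueError("need len(cutpoints)+1 labels")
    cuts = list(cutpoints)

    def fn(v):
        return labels[int(np.searchsorted(cuts, float(v), side="right"))]

    return fn


def generalize_value(h: Hierarchy, value, level: int):
    """Level-l label containing ``value``; level 0 returns it unchanged."""
    return h.generalize(value, level)
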