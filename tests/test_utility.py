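"""Information-loss metrics: calibration, hand cases, anti-monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anoncost import (IntervalSpec, build_category_hierarchy,
                      build_interval_hierarchy, granularity,
                      nonuniform_entropy, utility_report)
from conftest import make_table

ALL = "all kept"


def _one_var_table(values, domain=None):
    return make_table({"v": list(values)},
                      domains={"v": domain} if domain else None)


def _kept(n, suppressed=()):
    return [i for i in range(n) if i not in suppressed]


class TestGranularity:
    def test_identity_release_scores_100(self):
        t = _one_var_table([1, 2, 3, 4], (0, 10))
        h = build_interval_hierarchy(IntervalSpec(0, 10, 2, 2), "v")
        assert granularity(t, {"v": h}, ["v"], {"v": 0},
                           _kept(4)) == pytest.approx(100.0)

    def test_total_suppression_scores_0(self):
        t = _one_var_table([1, 2, 3, 4], (0, 10))
        h = build_interval_hierarchy(IntervalSpec(0, 10, 2, 2), "v")
        assert granularity(t, {"v": h}, ["v"], {"v": 1},
                           []) == pytest.approx(0.0)

    def test_two_value_classes_hand_case(self):
        # values 1..4 once each, generalized into two 2-value classes:
        # per-cell loss (2-1)/(4-1) = 1/3 -> 66.7%
        t = _one_var_table([1.0, 2.0, 3.0, 4.0], (1, 5))
        h = build_category_hierarchy("v", [{1.0: "lo", 2.0: "lo",
                                            3.0: "hi", 4.0: "hi"}])
        got = granularity(t, {"v": h}, ["v"], {"v": 1}, _kept(4))
        assert got == pytest.approx(100 * (1 - 1 / 3))

    def test_suppressed_records_lose_everything(self):
        t = _one_var_table([1.0, 2.0, 3.0, 4.0], (1, 5))
        h = build_category_hierarchy("v", [{1.0: "lo", 2.0: "lo",
                                            3.0: "hi", 4.0: "hi"}])
        got = granularity(t, {"v": h}, ["v"], {"v": 0}, _kept(4, {3}))
        assert got == pytest.approx(100 * (1 - 1 / 4))


class TestNonuniformEntropy:
    def test_identity_release_scores_100(self):
        t = _one_var_table(["A", "A", "B", "C"])
        h = build_category_hierarchy("v", [{"A": "A'", "B": "D", "C": "D"}])
        assert nonuniform_entropy(t, {"v": h}, ["v"], {"v": 0},
                                  _kept(4)) == pytest.approx(100.0)

    def test_total_suppression_scores_0(self):
        t = _one_var_table(["A", "A", "B", "C"])
        h = build_category_hierarchy("v", [{"A": "A'", "B": "D", "C": "D"}])
        assert nonuniform_entropy(t, {"v": h}, ["v"], {"v": 1},
                                  []) == pytest.approx(0.0)

    def test_merge_hand_case(self):
        # {A,A,B,C} with {B,C} -> "D": cell losses 0,0,1,1; maximum
        # (1+1+2+2) = 6 -> 100*(1-2/6) = 66.7%
        t = _one_var_table(["A", "A", "B", "C"])
        h = build_category_hierarchy("v", [{"A": "A'", "B": "D", "C": "D"}])
        got = nonuniform_entropy(t, {"v": h}, ["v"], {"v": 1}, _kept(4))
        assert got == pytest.approx(100 * (1 - 2 / 6))


class TestMonotonicityAndBounds:
    @settings(max_examples=200)
    @given(st.lists(st.integers(min_value=0, max_value=39), min_size=4,
                    max_size=40),
           st.integers(min_value=0, max_value=3),
           st.data())
    def test_both_metrics_anti_monotone_in_level(self, values, level, data):
        """Raising a variable's level never increases either metric."""
        t = _one_var_table(values, (0, 40))
        h = build_interval_hierarchy(IntervalSpec(0, 40, 5, 2), "v")
        if level + 1 > h.max_level:
            level = h.max_level - 1
        n_supp = data.draw(st.integers(min_value=0,
                                       max_value=len(values) // 3))
        kept = _kept(len(values), set(range(n_supp)))
        for metric in (granularity, nonuniform_entropy):
            lo = metric(t, {"v": h}, ["v"], {"v": level + 1}, kept)
            hi = metric(t, {"v": h}, ["v"], {"v": level}, kept)
            assert lo <= hi + 1e-9
            assert -1e-9 <= lo <= 100 + 1e-9

    def test_report_aggregates_per_variable(self):
        t = make_table({"a": [1.0, 2.0, 3.0, 4.0], "b": ["x", "x", "y", "y"]},
                       domains={"a": (0, 8), "b": ("x", "y")})
        h_a = build_interval_hierarchy(IntervalSpec(0, 8, 2, 2), "a")
        h_b = build_category_hierarchy("b", [{"x": "*", "y": "*"}])
        rep = utility_report(t, {"a": h_a, "b": h_b}, ["a", "b"],
                             {"a": 0, "b": 1}, _kept(4))
        assert rep.granularity_by_variable["a"] == pytest.approx(100.0)
        assert rep.entropy_by_variable["b"] == pytest.approx(0.0)
        assert rep.granularity_pct == pytest.approx(
            np.mean(list(rep.granularity_by_variable.values())))
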