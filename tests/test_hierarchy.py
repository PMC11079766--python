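"""Generalization hierarchies: anchoring, nestedness, label round-trip."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from anoncost import (IntervalSpec, build_category_hierarchy,
                      build_interval_hierarchy, generalize_value,
                      identity_hierarchy)
from anoncost.hierarchy import banded_map, parse_interval_label


class TestIntervalHierarchy:
    def test_level_zero_is_identity(self):
        h = build_interval_hierarchy(IntervalSpec(15, 80, 5, 2), "age")
        assert generalize_value(h, 47, 0) == 47

    def test_anchoring_at_domain_minimum(self):
        h = build_interval_hierarchy(IntervalSpec(15, 80, 5, 2), "age")
        assert generalize_value(h, 47, 1) == "[45,50)"
        assert generalize_value(h, 47, 2) == "[45,55)"  # merges [45,50)+[50,55)

    def test_anchor_arithmetic_from_other_minimum(self):
        h = build_interval_hierarchy(IntervalSpec(18, 80, 5, 2), "age")
        # the level with 10-year width is level 2 (5 * 2^1)
        assert generalize_value(h, 47, 2) == "[38,48)"

    def test_cap_restricts_generalization(self):
        h = build_interval_hierarchy(IntervalSpec(18, 80, 5, 2), "age", cap=2)
        assert h.max_level == 2
        assert generalize_value(h, 18, 2) == "[18,28)"
        with pytest.raises(ValueError):
            generalize_value(h, 18, 3)

    def test_uncapped_top_level_is_single_interval(self):
        h = build_interval_hierarchy(IntervalSpec(0, 160, 10, 2), "weight")
        top = h.max_level
        for v in (0, 37, 159.5, 160):
            assert generalize_value(h, v, top) == "[0,160]"

    def test_last_interval_closed_at_maximum(self):
        h = build_interval_hierarchy(IntervalSpec(15, 80, 5, 2), "age")
        assert generalize_value(h, 80, 1) == "[75,80]"

    def test_out_of_domain_rejected(self):
        h = build_interval_hierarchy(IntervalSpec(18, 80, 5, 2), "age")
        with pytest.raises(ValueError):
            generalize_value(h, 81, 1)
        with pytest.raises(ValueError):
            generalize_value(h, 17.9, 1)

    def test_degenerate_spec_rejected(self):
        with pytest.raises(ValueError):
            IntervalSpec(18, 80, 70, 2)
        with pytest.raises(ValueError):
            build_interval_hierarchy(IntervalSpec(18, 80, 5, 2), cap=0)

    @given(st.integers(min_value=0, max_value=65),
           st.integers(min_value=1, max_value=4))
    def test_nestedness(self, offset, level):
        """class(v, l+1) contains class(v, l) for every value and level."""
        h = build_interval_hierarchy(IntervalSpec(15, 80, 5, 2), "age")
        v = 15 + offset
        if level + 1 > h.max_level:
            return
        lo1, hi1, c1 = parse_interval_label(h.generalize(v, level))
        lo2, hi2, c2 = parse_interval_label(h.generalize(v, level + 1))
        assert lo2 <= lo1 and hi2 >= hi1

    @given(st.floats(min_value=15, max_value=80, allow_nan=False),
           st.integers(min_value=1, max_value=4))
    def test_label_round_trip_contains_value(self, v, level):
        h = build_interval_hierarchy(IntervalSpec(15, 80, 5, 2), "age")
        lo, hi, right_closed = parse_interval_label(h.generalize(v, level))
        assert lo <= v <= hi if right_closed else lo <= v < hi

    def test_lookup_table_has_one_column_per_level(self):
        h = build_interval_hierarchy(IntervalSpec(18, 80, 5, 2), "age", cap=2)
        tbl = h.lookup_table(range(18, 81))
        assert list(tbl.columns) == ["level_0", "level_1", "level_2"]
        assert tbl.loc[tbl["level_0"] == 47, "level_2"].iloc[0] == "[38,48)"


class TestCategoryHierarchy:
    def test_bmi_clinical_bands(self):
        h = build_category_hierarchy(
            "bmi", [banded_map((25.0, 30.0), ("<25.0", "25.0-29.9", "≥30.0"))])
        assert generalize_value(h, 27.3, 1) == "25.0-29.9"
        assert generalize_value(h, 24.9, 1) == "<25.0"
        assert generalize_value(h, 31.0, 1) == "≥30.0"
        assert generalize_value(h, 25.0, 1) == "25.0-29.9"

    def test_dichotomous_variables_cannot_be_generalized(self):
        h = identity_hierarchy("gender")
        assert h.max_level == 0
        assert generalize_value(h, "female", 0) == "female"
        with pytest.raises(ValueError):
            generalize_value(h, "female", 1)

    def test_map_based_levels_compose_and_check_totality(self):
        h = build_category_hierarchy("cause", [
            {"a": "ab", "b": "ab", "c": "cd", "d": "cd"},
            {"ab": "*", "cd": "*"},
        ])
        assert generalize_value(h, "c", 1) == "cd"
        assert generalize_value(h, "c", 2) == "*"
        with pytest.raises(ValueError):
            build_category_hierarchy("cause", [
                {"a": "ab", "b": "ab"},
                {"ab": "*", "zz": "*", "missing_parent": "*"},
            ][::-1])

    def test_non_total_second_level_rejected(self):
        with pytest.raises(ValueError):
            build_category_hierarchy("v", [
                {"a": "x", "b": "y"},
                {"x": "*"},  # y not covered
            ])
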