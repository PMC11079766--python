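"""Lattice search, scheme application and bounded suppression."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from anoncost import (GeneralizationScheme, IntervalSpec, PrivacyModel,
                      anonymize, apply_scheme, build_interval_hierarchy,
                      identity_hierarchy, suppress_to_satisfy)
from conftest import make_table
from oracles import search_oracle

AGE_H = build_interval_hierarchy(IntervalSpec(15, 80, 5, 2), "age")
F1_HIERARCHIES = {"age": AGE_H, "gender": identity_hierarchy("gender")}


def _scheme(**levels):
    qis = tuple(sorted(levels))
    return GeneralizationScheme(levels=tuple(levels[q] for q in qis), qis=qis)


class TestApplyScheme:
    def test_identity_scheme_leaves_table_unchanged(self, f1_table):
        out = apply_scheme(f1_table, F1_HIERARCHIES,
                           _scheme(age=0, gender=0))
        pd.testing.assert_frame_equal(out.df, f1_table.df)

    def test_generalizes_only_quasi_identifier_cells(self, f1_table):
        out = apply_scheme(f1_table, F1_HIERARCHIES,
                           _scheme(age=2, gender=0))
        assert out.df.loc[0, "age"] == "[45,55)"
        assert (out.df["egfr"] == f1_table.df["egfr"]).all()
        assert (out.df["gender"] == f1_table.df["gender"]).all()

    def test_ten_year_width_with_anchor_18(self):
        h = build_interval_hierarchy(IntervalSpec(18, 80, 5, 2), "age")
        t = make_table({"age": [47]}, domains={"age": (18, 80)})
        out = apply_scheme(t, {"age": h}, _scheme(age=2))
        assert out.df.loc[0, "age"] == "[38,48)"


class TestSuppressToSatisfy:
    def test_no_suppression_needed(self):
        t = make_table({"qi": ["A"] * 3 + ["B"] * 3})
        kept, n_supp, s, feasible = suppress_to_satisfy(
            t, ["qi"], PrivacyModel(0.5))
        assert n_supp == 0 and feasible
        assert s.pr_max == pytest.approx(1 / 3) and len(kept) == 6

    def test_singleton_suppression_can_exceed_budget(self):
        # classes {5,1}, k=2: the singleton must go, but 1/6 > 10%
        t = make_table({"qi": ["A"] * 5 + ["B"]})
        kept, n_supp, s, feasible = suppress_to_satisfy(
            t, ["qi"], PrivacyModel(0.5, suppression_limit=0.10))
        assert n_supp == 1
        assert not feasible
        assert s.pr_max == pytest.approx(0.2)

    def test_marketer_repair_removes_smallest_class(self):
        # classes {11,11,2}: avg risk 3/24 > 1/11; dropping the pair fixes it
        t = make_table({"qi": ["A"] * 11 + ["B"] * 11 + ["C"] * 2})
        kept, n_supp, s, feasible = suppress_to_satisfy(
            t, ["qi"], PrivacyModel(0.5, mr_threshold=1 / 11))
        assert n_supp == 2
        assert feasible
        assert s.pr_avg == pytest.approx(1 / 11)
        assert set(kept) == set(range(22))

    def test_every_kept_record_meets_group_size(self):
        rng = np.random.default_rng(7)
        t = make_table({"qi": rng.integers(0, 12, 120).tolist()})
        for thresh in (0.5, 1 / 11):
            kept, _, s, _ = suppress_to_satisfy(
                t, ["qi"], PrivacyModel(thresh, suppression_limit=1.0))
            counts = Counter(t.df.loc[kept, "qi"])
            k = int(1 / thresh + 1e-9)
            assert all(c >= k for c in counts.values())


class TestAnonymize:
    def test_unconstrained_threshold_returns_identity(self, f1_table):
        res = anonymize(f1_table, ("age", "gender"), F1_HIERARCHIES,
                        PrivacyModel(1.0))
        assert res.feasible
        assert res.scheme.as_dict() == {"age": 0, "gender": 0}
        assert res.n_suppressed == 0
        assert res.granularity_pct == pytest.approx(100.0)

    def test_empty_qi_set_returns_identity_result(self, f1_table):
        res = anonymize(f1_table, (), {}, PrivacyModel(0.5))
        assert res.feasible and res.n_suppressed == 0

    def test_impossible_constraint_reported_infeasible(self, f1_table):
        res = anonymize(f1_table, ("age", "gender"), F1_HIERARCHIES,
                        PrivacyModel(0.05, suppression_limit=0.0))
        assert not res.feasible  # k=20 > n=8 and no suppression allowed

    def test_f1_fixture_matches_exhaustive_oracle(self, f1_table):
        model = PrivacyModel(0.5, suppression_limit=0.25)
        res = anonymize(f1_table, ("age", "gender"), F1_HIERARCHIES, model)
        oracle = search_oracle(f1_table.df, ("age", "gender"), F1_HIERARCHIES,
                               0.5, None, 0.25)
        assert oracle is not None
        levels, n_supp, gran = oracle
        assert res.feasible
        assert tuple(res.scheme.levels) == levels
        assert res.n_suppressed == n_supp
        assert res.granularity_pct == pytest.approx(gran)

    def test_released_records_keep_group_size_guarantee(self, f1_table):
        """Brute-force k-anonymity scan of the released table."""
        model = PrivacyModel(0.5, suppression_limit=0.25)
        res = anonymize(f1_table, ("age", "gender"), F1_HIERARCHIES, model)
        tuples = list(zip(res.table.df["age"], res.table.df["gender"]))
        counts = Counter(tuples)
        assert all(counts[t] >= 2 for t in tuples)

    def test_random_small_instances_match_oracle(self):
        """Search equals exhaustive enumeration with the documented tie rule."""
        rng = np.random.default_rng(2024)
        age_h = build_interval_hierarchy(IntervalSpec(20, 60, 5, 2), "age")
        hs = {"age": age_h, "gender": identity_hierarchy("gender")}
        for trial in range(20):
            n = int(rng.integers(6, 40))
            t = make_table({
                "age": rng.integers(20, 61, n).tolist(),
                "gender": rng.choice(["m", "f"], n).tolist(),
            }, kinds={"gender": "dichotomous"},
                domains={"age": (20, 60), "gender": ("f", "m")})
            thresh = float(rng.choice([0.5, 1 / 3, 0.2]))
            mr = float(rng.choice([0.5, 0.25])) if rng.random() < 0.4 else None
            mr = min(mr, thresh) if mr is not None else None
            model = PrivacyModel(thresh, mr_threshold=mr,
                                 suppression_limit=0.2)
            res = anonymize(t, ("age", "gender"), hs, model)
            oracle = search_oracle(t.df, ("age", "gender"), hs,
                                   thresh, mr, 0.2)
            if oracle is None:
                assert not res.feasible
            else:
                levels, n_supp, gran = oracle
                assert res.feasible
                assert tuple(res.scheme.levels) == levels
                assert res.n_suppressed == n_supp
                assert res.granularity_pct == pytest.approx(gran)

    def test_tightening_threshold_never_improves_granularity(self, f1_table):
        grans = []
        for t in (1.0, 0.5, 1 / 3, 0.25):
            res = anonymize(f1_table, ("age", "gender"), F1_HIERARCHIES,
                            PrivacyModel(t, suppression_limit=0.25))
            if res.feasible:
                grans.append(res.granularity_pct)
        assert grans == sorted(grans, reverse=True)
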