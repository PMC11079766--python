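"""Scenario configuration, threshold sweeps and curve exports."""

import numpy as np
import pandas as pd
import pytest

from anoncost import (CohortParams, curve_export, generate_cohort,
                      load_scenario, sweep)
from anoncost.scenarios import export_hierarchies, generic_scenario, \
    use_case_scenario


@pytest.fixture(scope="module")
def small_cohort():
    return generate_cohort(CohortParams(n=600, seed=9))


class TestScenarioConfigs:
    def test_generic_structure(self):
        cfg = generic_scenario()
        assert cfg.qis == ("age", "gender", "height", "renal_biopsy", "weight")
        assert cfg.removed == ("bmi",)
        # unrestricted generalization: top level is a single interval
        age = cfg.hierarchies["age"]
        assert age.generalize(40, age.max_level) == "[15,80]"
        assert cfg.hierarchies["gender"].max_level == 0

    def test_use_case_structure(self):
        cfg = use_case_scenario()
        assert cfg.qis == ("age", "bmi", "gender", "renal_biopsy")
        assert cfg.removed == ("height", "weight")
        age = cfg.hierarchies["age"]
        assert age.max_level == 2  # capped at 10-year intervals
        assert age.generalize(47, 2) == "[38,48)"
        bmi = cfg.hierarchies["bmi"]
        assert bmi.max_level == 1
        assert bmi.generalize(27.3, 1) == "25.0-29.9"

    def test_yaml_round_trip(self, tmp_path):
        y = tmp_path / "scen.yaml"
        y.write_text(
            "name: custom\n"
            "interdependence: use_case\n"
            "suppression_limit: 0.05\n"
            "hierarchies:\n"
            "  age: {kind: interval, min: 18, max: 80, base_width: 5, cap: 2}\n"
            "  bmi: {kind: banded, cutpoints: [25.0, 30.0],\n"
            "        labels: ['<25.0', '25.0-29.9', '>=30.0']}\n"
            "  gender: {kind: identity}\n"
            "  renal_biopsy: {kind: identity}\n")
        cfg = load_scenario(y)
        assert cfg.name == "custom"
        assert cfg.suppression_limit == 0.05
        assert cfg.qis == ("age", "bmi", "gender", "renal_biopsy")
        assert cfg.hierarchies["age"].generalize(47, 2) == "[38,48)"

    def test_yaml_missing_hierarchy_rejected(self, tmp_path):
        y = tmp_path / "scen.yaml"
        y.write_text("name: bad\ninterdependence: generic\n"
                     "hierarchies:\n  age: {kind: identity}\n")
        with pytest.raises(ValueError):
            load_scenario(y)

    def test_hierarchy_export_round_trip(self, tmp_path):
        cfg = use_case_scenario()
        paths = export_hierarchies(
            cfg, {"age": list(range(18, 81)), "bmi": [20.0, 27.0, 35.0],
                  "gender": ["female", "male"],
                  "renal_biopsy": ["no", "yes"]}, tmp_path)
        assert len(paths) == 4
        age_tbl = pd.read_csv([p for p in paths if "age" in p.name][0])
        assert "level_2" in age_tbl.columns


class TestSweep:
    def test_unconstrained_grid(self, small_cohort, scenarios):
        rows = sweep(small_cohort, scenarios, grid=(1.0,),
                     include_highlights=False)
        assert len(rows) == 2
        assert (rows["n_suppressed"] == 0).all()
        assert np.allclose(rows["granularity_pct"], 100.0)
        assert np.allclose(rows["entropy_pct"], 100.0)
        assert np.allclose(rows["overall_cio_pct"], 100.0)

    def test_row_count_is_grid_times_scenarios(self, small_cohort, scenarios):
        grid = (1.0, 0.5, 0.25)
        rows = sweep(small_cohort, scenarios, grid=grid,
                     include_highlights=False)
        assert len(rows) == len(grid) * 2

    def test_tightening_thresholds_never_raises_granularity(
            self, small_cohort, scenarios):
        grid = (1.0, 0.5, 1 / 3, 0.25, 0.2, 1 / 6)
        rows = sweep(small_cohort, scenarios, grid=grid,
                     include_highlights=False)
        for _, sub in rows.groupby("scenario"):
            feas = sub[sub["feasible"]]
            g = feas["granularity_pct"].to_numpy()
            assert (np.diff(g) <= 1e-9).all()

    def test_end_to_end_determinism(self, small_cohort, scenarios, tmp_path):
        grid = (0.5, 0.25)
        outs = []
        for i in (1, 2):
            rows = sweep(small_cohort, scenarios, grid=grid)
            p = tmp_path / f"s{i}.csv"
            rows.to_csv(p, index=False)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_marketer_family_bounds_average_risk(self, small_cohort,
                                                 scenarios):
        rows = sweep(small_cohort, scenarios, grid=(0.25, 0.1),
                     family="pr_mr", include_highlights=False)
        feas = rows[rows["feasible"]]
        assert (feas["pr_avg"] <= feas["mr_threshold"] + 1e-9).all()
        assert (feas["pr_max"] <= 0.5 + 1e-9).all()


class TestCurveExport:
    def test_single_row_gets_anchor_points(self, small_cohort, scenarios):
        rows = sweep(small_cohort, scenarios[:1], grid=(0.5,),
                     include_highlights=False)
        curves = curve_export(rows)
        assert len(curves) == 9  # 3 metrics x 3 privacy axes
        for tbl in curves.values():
            assert len(tbl) == 3
            anchors = tbl[~tbl["measured"]]
            assert set(map(tuple, anchors[["privacy_pct",
                                           "utility_pct"]].values)) == \
                {(0.0, 100.0), (100.0, 0.0)}
            assert (tbl["privacy_pct"].diff().dropna() >= 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            curve_export(pd.DataFrame())
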