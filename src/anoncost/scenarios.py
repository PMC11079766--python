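"""Scenario configurations: quasi-identifiers, hierarchies and caps.

Two built-in scenarios bracket the design space:

* **generic** — supports unspecified downstream uses: age, height and
  weight are generalizable without restriction (up to a single top
  interval); BMI is removed to break the anthropometric interdependence.
* **use_case** — tailored to the descriptive CKD analyses: age
  generalization is capped at 10-year intervals, BMI is kept and coarsened
  only into the three clinical categories (<25.0, 25.0-29.9, >=30.0),
  height and weight are removed.

Gender and renal-biopsy history are dichotomous and never generalized; the
anonymizer can only suppress records carrying them. Scenarios can also be
declared in YAML with the same fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .hierarchy import (Hierarchy, IntervalSpec, banded_map,
                        build_category_hierarchy, build_interval_hierarchy,
                        identity_hierarchy)
from .risk import PrivacyModel
from .threat_model import (QiDecision, RiskProfile, default_risk_profiles,
                           score_variable, select_quasi_identifiers)

BMI_CATEGORY_LABELS = ("<25.0", "25.0-29.9", "≥30.0")
BMI_CATEGORY_CUTPOINTS = (25.0, 30.0)


@dataclass
class ScenarioConfig:
    name: str
    qis: tuple[str, ...]  # after interdependence removal, sorted
    removed: tuple[str, ...]
    hierarchies: dict[str, Hierarchy] = field(repr=False)
    suppression_limit: float = 0.10
    seed: int = 42

    def model(self, pr_threshold: float,
              mr_threshold: float | None = None) -> PrivacyModel:
        return PrivacyModel(pr_threshold=pr_threshold,
                            mr_threshold=mr_threshold,
                            suppression_limit=self.suppression_limit)


def _qi_sets(scenario: str,
             profiles: list[RiskProfile] | None = None
             ) -> tuple[tuple[str, ...], tuple[str, ...]]:
    profiles = profiles or default_risk_profiles()
    decisions: list[QiDecision] = [score_variable(p) for p in profiles]
    qis, removed = select_quasi_identifiers(decisions, scenario)
    return tuple(sorted(qis)), tuple(sorted(removed))


def generic_scenario(suppression_limit: float = 0.10,
                     seed: int = 42) -> ScenarioConfig:
    """Unrestricted generalization; BMI removed."""
    qis, removed = _qi_sets("generic")
    hierarchies = {
        "age": build_interval_hierarchy(
            IntervalSpec(15, 80, 5, 2), variable="age"),
        "height": build_interval_hierarchy(
            IntervalSpec(20, 280, 10, 2), variable="height"),
        "weight": build_interval_hierarchy(
            IntervalSpec(0, 160, 10, 2), variable="weight"),
        "gender": identity_hierarchy("gender"),
        "renal_biopsy": identity_hierarchy("renal_biopsy"),
    }
    return ScenarioConfig(name="generic", qis=qis, removed=removed,
                          hierarchies=hierarchies,
                          suppression_limit=suppression_limit, seed=seed)


def use_case_scenario(suppression_limit: float = 0.10,
                      seed: int = 42) -> ScenarioConfig:
    """Generalization capped to analysis-relevant resolution; height and
    weight removed in favour of BMI."""
    qis, removed = _qi_sets("use_case")
    hierarchies = {
        "age": build_interval_hierarchy(
            IntervalSpec(18, 80, 5, 2), variable="age", cap=2),  # <=10-year
        "bmi": build_category_hierarchy(
            "bmi", [banded_map(BMI_CATEGORY_CUTPOINTS, BMI_CATEGORY_LABELS)]),
        "gender": identity_hierarchy("gender"),
        "renal_biopsy": identity_hierarchy("renal_biopsy"),
    }
    return ScenarioConfig(name="use_case", qis=qis, removed=removed,
                          hierarchies=hierarchies,
                          suppression_limit=suppression_limit, seed=seed)


def builtin_scenarios(suppression_limit: float = 0.10,
                      seed: int = 42) -> list[ScenarioConfig]:
    return [generic_scenario(suppression_limit, seed),
            use_case_scenario(suppression_limit, seed)]


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Build a ScenarioConfig from a YAML declaration.

    Schema::

        name: my_scenario
        suppression_limit: 0.10
        threat_model:                # optional; defaults used when absent
          - {variable: age, availability: 3, replicability: 3, distinguishability: 2}
        interdependence: generic     # which removal rule to apply
        hierarchies:
          age: {kind: interval, min: 15, max: 80, base_width: 5,
                grouping_factor: 2, cap: null}
          bmi: {kind: banded, cutpoints: [25.0, 30.0],
                labels: ["<25.0", "25.0-29.9", "≥30.0"]}
          gender: {kind: identity}
    """
    raw = yaml.safe_load(Path(path).read_text())
    name = raw["name"]
    profiles = None
    if "threat_model" in raw:
        profiles = [RiskProfile(p["variable"], p["availability"],
                                p["replicability"], p["distinguishability"])
                    for p in raw["threat_model"]]
    scenario_kind = raw.get("interdependence", name)
    qis, removed = _qi_sets(scenario_kind, profiles)
    hierarchies: dict[str, Hierarchy] = {}
    for var, h in raw["hierarchies"].items():
        kind = h["kind"]
        if kind == "interval":
            hierarchies[var] = build_interval_hierarchy(
                IntervalSpec(h["min"], h["max"], h["base_width"],
                             h.get("grouping_factor", 2)),
                variable=var, cap=h.get("cap"))
        elif kind == "banded":
            hierarchies[var] = build_category_hierarchy(
                var, [banded_map(h["cutpoints"], h["labels"])])
        elif kind == "identity":
            hierarchies[var] = identity_hierarchy(var)
        else:
            raise ValueError(f"unknown hierarchy kind {kind!r} for {var}")
    missing = set(qis) - set(hierarchies)
    if missing:
        raise ValueError(f"no hierarchy declared for {sorted(missing)}")
    return ScenarioConfig(name=name, qis=qis, removed=removed,
                          hierarchies=hierarchies,
                          suppression_limit=raw.get("suppression_limit", 0.10),
                          seed=raw.get("seed", 42))


def export_hierarchies(config: ScenarioConfig,
                       values_by_var: Mapping[str, list],
                       out_dir: str | Path) -> list[Path]:
    """Write each hierarchy as a flat CSV lookup (one column per level)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for var in config.qis:
        h = config.hierarchies[var]
        tbl = h.lookup_table(values_by_var[var])
        p = out_dir / f"hierarchy_{config.name}_{var}.csv"
        tbl.to_csv(p, index=False)
        written.append(p)
    return written
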