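"""Semiquantitative quasi-identifier detection.

Each variable is profiled on three ordinal components — availability (how
likely an adversary already knows it), replicability (how stably it recurs
for the same person) and distinguishability (how strongly it separates
individuals) — each scored 1 (low) to 3 (high). The component sum is the
variable's risk score and a score strictly greater than 5 flags the variable
as "risky", i.e. a quasi-identifier candidate.

Interdependent variables (here the anthropometric triple height/weight/BMI)
cannot be generalized independently without leaking information through
back-calculation, so one side of the dependency is removed from the released
data: the generic scenario keeps height and weight and drops BMI, the
use-case scenario keeps BMI and drops height and weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

RISKY_SCORE_THRESHOLD = 5  # risky iff score strictly greater

Scenario = Literal["generic", "use_case"]

# variables removed per scenario to break the height/weight/BMI dependency
INTERDEPENDENCE_REMOVALS: dict[str, frozenset[str]] = {
    "generic": frozenset({"bmi"}),
    "use_case": frozenset({"height", "weight"}),
}


@dataclass(frozen=True)
class RiskProfile:
    variable: str
    availability: int
    replicability: int
    distinguishability: int

    def __post_init__(self) -> None:
        for comp in (self.availability, self.replicability,
                     self.distinguishability):
            if comp not in (1, 2, 3):
                raise ValueError(
                    f"{self.variable}: components must be in {{1,2,3}}")


@dataclass(frozen=True)
class QiDecision:
    variable: str
    score: int
    risky: bool


def score_variable(profile: RiskProfile) -> QiDecision:
    """Sum the three components; risky iff the sum exceeds 5."""
    score = (profile.availability + profile.replicability
             + profile.distinguishability)
    return QiDecision(variable=profile.variable, score=score,
                      risky=score > RISKY_SCORE_THRESHOLD)


def select_quasi_identifiers(
    decisions: Iterable[QiDecision],
    scenario: Scenario,
    extra_removals: Iterable[str] = (),
) -> tuple[set[str], set[str]]:
    """Split risky variables into the quasi-identifier set and removals.

    Returns ``(qis, removed)``: risky variables minus the scenario's
    interdependence removals, and the removed risky variables. Variables in
    ``extra_removals`` let callers declare further derived-variable
    dependencies beyond the built-in anthropometric triple. A variable is
    only ever removed if it was flagged risky in the first place.
    """
    if scenario not in INTERDEPENDENCE_REMOVALS:
        raise ValueError(f"unknown scenario: {scenario!r}")
    risky = {dec.variable for dec in decisions if dec.risky}
    to_remove = INTERDEPENDENCE_REMOVALS[scenario] | set(extra_removals)
    removed = risky & to_remove
    return risky - removed, removed


def default_risk_profiles() -> list[RiskProfile]:
    """Shipped component scores for the synthetic cohort's core variables.

    These are illustrative defaults (not authoritative expert scores) chosen
    so the screening flags exactly the six demographically linkable
    variables: age, gender, height, weight, BMI and renal-biopsy history.
    Clinical measurements score low on availability and replicability.
    """
    return [
        RiskProfile("age", 3, 3, 2),
        RiskProfile("gender", 3, 3, 1),
        RiskProfile("height", 2, 3, 2),
        RiskProfile("weight", 2, 2, 2),
        RiskProfile("bmi", 2, 2, 2),
        RiskProfile("renal_biopsy", 2, 2, 2),
        RiskProfile("diabetes", 2, 2, 1),
        RiskProfile("egfr", 1, 1, 3),
        RiskProfile("uacr_category", 1, 1, 1),
        RiskProfile("systolic_bp", 1, 1, 2),
        RiskProfile("ace_inhibitor", 1, 2, 1),
        RiskProfile("arb", 1, 2, 1),
        RiskProfile("statin", 1, 2, 1),
        RiskProfile("diuretic", 1, 2, 1),
        RiskProfile("ckd_cause", 1, 2, 2),
    ]
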