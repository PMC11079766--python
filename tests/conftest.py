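import pandas as pd
import pytest
from hypothesis import settings

from anoncost import (CohortTable, VariableMeta, builtin_scenarios,
                      generate_cohort)
from anoncost.cohort import QUASI_IDENTIFIERS

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

QIS = QUASI_IDENTIFIERS


@pytest.fixture(scope="session")
def full_cohort():
    """Default synthetic cohort: 5217 records x 70 variables, seed 42."""
    return generate_cohort()


@pytest.fixture(scope="session")
def scenarios():
    return builtin_scenarios()


def make_table(columns: dict[str, list], kinds: dict[str, str] | None = None,
               domains: dict[str, tuple] | None = None) -> CohortTable:
    """Small hand-built cohort table for worked examples."""
    kinds = kinds or {}
    domains = domains or {}
    meta = []
    for name, vals in columns.items():
        kind = kinds.get(name)
        series = pd.Series(vals)
        if kind is None:
            kind = "continuous" if series.dtype.kind in "if" else "categorical"
        if name in domains:
            domain = domains[name]
        elif kind == "continuous":
            domain = (float(series.min()), float(series.max()) + 1)
        else:
            domain = tuple(sorted(series.dropna().unique()))
        meta.append(VariableMeta(name, kind, "", domain))
    return CohortTable(df=pd.DataFrame(columns), meta=meta)


@pytest.fixture
def f1_table():
    """Eight-record worked example over age + gender quasi-identifiers.

    Ages cluster so that a small amount of generalization creates classes of
    size >= 2 while one record stays hard to protect.
    """
    return make_table({
        "age": [47, 47, 48, 52, 53, 61, 61, 33],
        "gender": ["male", "male", "male", "female", "female",
                   "female", "female", "male"],
        "egfr": [50.0, 60.0, 55.0, 40.0, 45.0, 70.0, 65.0, 30.0],
    }, kinds={"gender": "dichotomous", "egfr": "continuous"},
        domains={"age": (15, 80), "gender": ("female", "male")})
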