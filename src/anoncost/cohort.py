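"""Synthetic clinical cohort tables.

The confidential study extract this package analyses cannot be shipped, so a
seeded generator emulates its statistical structure: a rectangular table of
records x variables with six quasi-identifiers (age, gender, height, weight,
BMI, renal-biopsy history), near-total uniqueness of the quasi-identifier
combination, an interdependent height/weight/BMI triple, and CKD-flavoured
analysis variables whose distributions shift with diabetes status.

The table is carried as a :class:`pandas.DataFrame` wrapped together with
per-variable metadata in :class:`CohortTable`; missing cells are NaN in
memory and empty fields on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import defaults as d

QUASI_IDENTIFIERS = ("age", "gender", "height", "weight", "bmi", "renal_biopsy")

VariableKind = str  # {"continuous", "categorical", "dichotomous"}


@dataclass(frozen=True)
class VariableMeta:
    """Metadata for one cohort variable."""

    name: str
    kind: VariableKind
    unit: str = ""
    domain: tuple = ()  # value list (categorical) or (min, max) bounds
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical", "dichotomous"):
            raise ValueError(f"unknown variable kind: {self.kind!r}")
        if not self.domain:
            raise ValueError(f"{self.name}: domain must be non-empty")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.name}: missing_rate outside [0,1]")
        if self.kind == "dichotomous" and len(self.domain) != 2:
            raise ValueError(f"{self.name}: dichotomous needs exactly 2 levels")
        if self.kind == "continuous" and len(self.domain) != 2:
            raise ValueError(f"{self.name}: continuous domain is (min, max)")


@dataclass
class CohortTable:
    """A records x variables table plus per-variable metadata."""

    df: pd.DataFrame
    meta: list[VariableMeta]

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            raise ValueError("cohort table must have at least one record")
        names = [m.name for m in self.meta]
        if list(self.df.columns) != names:
            raise ValueError("metadata order must match table columns")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def variables(self) -> list[str]:
        return list(self.df.columns)

    def meta_for(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    # --- persistence -------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV (missing -> empty field) + JSON sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False, na_rep="")
        sidecar = [
            {
                "name": m.name,
                "kind": m.kind,
                "unit": m.unit,
                "domain": list(m.domain),
                "missing_rate": m.missing_rate,
            }
            for m in self.meta
        ]
        path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".meta.json").read_text())
        meta = [
            VariableMeta(
                name=m["name"],
                kind=m["kind"],
                unit=m.get("unit", ""),
                domain=tuple(m["domain"]),
                missing_rate=m.get("missing_rate", 0.0),
            )
            for m in sidecar
        ]
        dtypes = {
            m.name: (float if m.kind == "continuous" else object) for m in meta
        }
        df = pd.read_csv(path, dtype=dtypes, keep_default_na=True)
        return cls(df=df, meta=meta)

    def validate(self) -> None:
        """Check every cell against its domain and the BMI consistency rule."""
        for m in self.meta:
            col = self.df[m.name]
            present = col.dropna()
            if m.kind == "continuous":
                lo, hi = m.domain
                bad = present[(present < lo) | (present > hi)]
                if len(bad):
                    raise ValueError(f"{m.name}: {len(bad)} cells out of bounds")
            else:
                extra = set(present.unique()) - set(m.domain)
                if extra:
                    raise ValueError(f"{m.name}: unexpected values {extra}")
        if {"height", "weight", "bmi"} <= set(self.df.columns):
            sub = self.df[["height", "weight", "bmi"]].dropna()
            expected = (sub["weight"] / (sub["height"] / 100.0) ** 2).round(1)
            if not np.allclose(sub["bmi"], expected):
                raise ValueError("BMI inconsistent with height and weight")


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; defaults mirror the emulated study extract."""

    n: int = d.N_RECORDS
    seed: int = d.DEFAULT_SEED
    n_columns: int = d.N_COLUMNS
    qi_missing_rate: float = 0.0
    male_p: float = d.MALE_P
    diabetes_p: float = d.DIABETES_P
    renal_biopsy_p: float = d.RENAL_BIOPSY_P
    uacr_probs: dict = field(default_factory=lambda: dict(d.UACR_PROBS))
    ckd_cause_probs: dict = field(default_factory=lambda: dict(d.CKD_CAUSE_PROBS))

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for p in (self.male_p, self.diabetes_p, self.renal_biopsy_p,
                  self.qi_missing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0,1]")
        for probs in (self.uacr_probs, self.ckd_cause_probs):
            for key, vec in probs.items():
                v = np.asarray(vec, dtype=float)
                if (v < 0).any() or (v > 1).any() or abs(v.sum() - 1.0) > 1e-9:
                    raise ValueError(f"invalid probability vector for {key!r}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal; bounds are a few sd wide here."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _inject_missing(rng: np.random.Generator, values: np.ndarray,
                    rate: float) -> np.ndarray:
    if rate <= 0:
        return values
    out = values.astype(object)
    out[rng.random(len(values)) < rate] = np.nan
    return out


def generate_cohort(params: CohortParams | None = None) -> CohortTable:
    """Generate a seeded synthetic cohort table.

    Quasi-identifiers are produced at measurement resolution (age in whole
    years, height/weight to 1 unit, BMI to 0.1) because resolution drives
    uniqueness of the quasi-identifier combination. Weight comes from a
    latent BMI times squared height, so height, weight and the recorded BMI
    column are mutually consistent: bmi == round(weight/(height/100)^2, 1)
    wherever all three are present.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    n = params.n

    age = np.round(_truncated_normal(rng, d.AGE_MEAN, d.AGE_SD,
                                     *d.AGE_RANGE, size=n)).astype(int)
    gender = np.where(rng.random(n) < params.male_p, "male", "female")

    height = np.empty(n)
    for g, (mu, sd) in d.HEIGHT_BY_GENDER.items():
        mask = gender == g
        height[mask] = _truncated_normal(rng, mu, sd, *d.HEIGHT_RANGE,
                                         size=int(mask.sum()))
    height = np.round(height).astype(int)

    latent_bmi = _truncated_normal(rng, d.LATENT_BMI_MEAN, d.LATENT_BMI_SD,
                                   *d.LATENT_BMI_RANGE, size=n)
    weight = np.round(latent_bmi * (height / 100.0) ** 2)
    # keep weight inside its domain and the recorded BMI inside its own
    h2 = (height / 100.0) ** 2
    weight = np.clip(weight, np.maximum(d.WEIGHT_RANGE[0],
                                        np.ceil((d.BMI_RANGE[0] + 0.05) * h2)),
                     np.minimum(d.WEIGHT_RANGE[1],
                                np.floor((d.BMI_RANGE[1] - 0.05) * h2)))
    weight = weight.astype(int)
    bmi = np.round(weight / h2, 1)

    renal_biopsy = np.where(rng.random(n) < params.renal_biopsy_p, "yes", "no")
    diabetes = np.where(rng.random(n) < params.diabetes_p, "yes", "no")
    diab = diabetes == "yes"

    egfr = np.round(_truncated_normal(
        rng, d.EGFR_MEAN, d.EGFR_SD, *d.EGFR_RANGE, size=n)
        + np.where(diab, d.EGFR_DIABETES_SHIFT, 0.0))
    egfr = np.clip(egfr, *d.EGFR_RANGE).astype(int)

    uacr = np.empty(n, dtype=object)
    for g in ("no", "yes"):
        mask = diabetes == g
        uacr[mask] = rng.choice(d.UACR_LEVELS, size=int(mask.sum()),
                                p=params.uacr_probs[g])

    sbp = np.round(_truncated_normal(rng, d.SBP_MEAN, d.SBP_SD,
                                     *d.SBP_RANGE, size=n)
                   + np.where(diab, d.SBP_DIABETES_SHIFT, 0.0))
    sbp = np.clip(sbp, *d.SBP_RANGE).astype(int)

    meds = {}
    for name, p in d.MEDICATION_PROBS.items():
        pv = np.full(n, p)
        if name == "statin":
            pv = pv + np.where(diab, d.MEDICATION_STATIN_DIABETES_SHIFT, 0.0)
        meds[name] = np.where(rng.random(n) < pv, "yes", "no")

    cause = np.empty(n, dtype=object)
    for g in ("no", "yes"):
        mask = diabetes == g
        cause[mask] = rng.choice(d.CKD_CAUSE_LEVELS, size=int(mask.sum()),
                                 p=params.ckd_cause_probs[g])

    columns: dict[str, np.ndarray] = {
        "age": _inject_missing(rng, age, params.qi_missing_rate),
        "gender": _inject_missing(rng, gender, params.qi_missing_rate),
        "height": _inject_missing(rng, height, params.qi_missing_rate),
        "weight": _inject_missing(rng, weight, params.qi_missing_rate),
        "bmi": _inject_missing(rng, bmi, params.qi_missing_rate),
        "renal_biopsy": _inject_missing(rng, renal_biopsy,
                                        params.qi_missing_rate),
        "diabetes": diabetes,
        "egfr": _inject_missing(rng, egfr, d.EGFR_MISSING_RATE),
        "uacr_category": _inject_missing(rng, uacr, d.UACR_MISSING_RATE),
        "systolic_bp": _inject_missing(rng, sbp, d.SBP_MISSING_RATE),
        **meds,
        "ckd_cause": _inject_missing(rng, cause, d.CKD_CAUSE_MISSING_RATE),
    }

    meta = [
        VariableMeta("age", "continuous", "years", d.AGE_RANGE,
                     params.qi_missing_rate),
        VariableMeta("gender", "dichotomous", "", d.GENDER_LEVELS,
                     params.qi_missing_rate),
        VariableMeta("height", "continuous", "cm", d.HEIGHT_RANGE,
                     params.qi_missing_rate),
        VariableMeta("weight", "continuous", "kg", d.WEIGHT_RANGE,
                     params.qi_missing_rate),
        VariableMeta("bmi", "continuous", "kg/m²", d.BMI_RANGE,
                     params.qi_missing_rate),
        VariableMeta("renal_biopsy", "dichotomous", "", d.RENAL_BIOPSY_LEVELS,
                     params.qi_missing_rate),
        VariableMeta("diabetes", "dichotomous", "", d.DIABETES_LEVELS),
        VariableMeta("egfr", "continuous", "mL/min", d.EGFR_RANGE,
                     d.EGFR_MISSING_RATE),
        VariableMeta("uacr_category", "categorical", "mg/g", d.UACR_LEVELS,
                     d.UACR_MISSING_RATE),
        VariableMeta("systolic_bp", "continuous", "mm Hg", d.SBP_RANGE,
                     d.SBP_MISSING_RATE),
        *[VariableMeta(nm, "dichotomous", "", d.MEDICATION_LEVELS,
                       d.MEDICATION_MISSING_RATE) for nm in meds],
        VariableMeta("ckd_cause", "categorical", "", d.CKD_CAUSE_LEVELS,
                     d.CKD_CAUSE_MISSING_RATE),
    ]

    # pad with inert filler columns up to the requested width
    filler_count = params.n_columns - len(columns)
    if filler_count < 0:
        raise ValueError("n_columns smaller than the core variable count")
    for i in range(filler_count):
        nm = f"filler_{i + 1:02d}"
        if i % 2 == 0:
            vals = np.where(rng.random(n) < d.FILLER_BINARY_P, "yes", "no")
            meta.append(VariableMeta(nm, "dichotomous", "", ("no", "yes"),
                                     d.FILLER_MISSING_RATE))
        else:
            vals = np.round(rng.normal(d.FILLER_CONTINUOUS_MEAN,
                                       d.FILLER_CONTINUOUS_SD, n), 2)
            meta.append(VariableMeta(nm, "continuous", "", (-6.0, 6.0),
                                     d.FILLER_MISSING_RATE))
        columns[nm] = _inject_missing(rng, vals, d.FILLER_MISSING_RATE)

    df = pd.DataFrame(columns)
    return CohortTable(df=df, meta=meta)


def uniqueness_fraction(table: CohortTable, qis: Sequence[str]) -> float:
    """Fraction of records whose quasi-identifier tuple occurs exactly once."""
    qis = list(qis)
    unknown = set(qis) - set(table.variables)
    if unknown:
        raise KeyError(f"unknown variables: {sorted(unknown)}")
    sizes = table.df.groupby(qis, dropna=False, observed=True)[
        qis[0]].transform("size")
    return float((sizes == 1).mean())
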