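"""Cohort schema and table container.

A cohort is a flat patient table: one row per patient, 22 predictor columns
(demographics, etiology, perioperative and coagulation indicators, and
postoperative recanalization rates) plus a binary outcome column recording
stent occlusion within one year of iliac-vein stenting.

Each variable carries a *kind* that drives downstream behaviour: which
summary statistic describes it, which two-sample test compares it between
splits, and how it is encoded for modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VALID_KINDS = {"continuous_normal", "continuous_skewed", "binary", "categorical", "count"}

OUTCOME = "stent_occlusion"


class SchemaError(ValueError):
    """Raised when a table does not conform to its declared schema."""


class ValidationError(ValueError):
    """Raised when a value violates a physical-range invariant."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one cohort variable.

    Parameters
    ----------
    name : str
        Column name, unique within a schema.
    kind : str
        One of ``continuous_normal``, ``continuous_skewed``, ``binary``,
        ``categorical``, ``count``.
    units : str
        Free-text units ("years", "mm", "mg/L", "%", ...). Empty for
        dimensionless variables.
    categories : tuple of str
        Ordered level labels; required (>= 2 levels) for categorical
        variables, empty otherwise.
    bounds : tuple of float
        Inclusive physical range ``(low, high)``; ``(-inf, inf)`` when
        unconstrained.
    """

    name: str
    kind: str
    units: str = ""
    categories: tuple[str, ...] = ()
    bounds: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise SchemaError(f"unknown variable kind {self.kind!r} for {self.name!r}")
        if self.kind == "categorical" and len(self.categories) < 2:
            raise SchemaError(f"categorical variable {self.name!r} needs >= 2 categories")
        if self.kind != "categorical" and self.categories:
            raise SchemaError(f"{self.name!r}: only categorical variables take categories")
        if not self.bounds[0] <= self.bounds[1]:
            raise SchemaError(f"{self.name!r}: bounds must be ordered")


# The study's predictor set.  Etiology levels run from post-thrombotic
# syndrome alone to the highest-risk DVT + Cockett + PE triad; recanalization
# rates are percent restoration of flow at the 30-day ultrasound.
ETIOLOGY_LEVELS = ("PTS", "DVT", "Cockett", "DVT + Cockett", "DVT + Cockett + PE")
ANTICOAG_LEVELS = ("warfarin", "NOAC", "none")


def default_schema() -> list[VariableSchema]:
    """The 22-predictor schema of the stent-occlusion cohort."""
    V = VariableSchema
    pos = (np.nextafter(0.0, 1.0), np.inf)  # strictly positive
    pct = (0.0, 100.0)
    return [
        V("male", "binary"),
        V("age", "continuous_normal", "years", bounds=pos),
        V("bmi", "continuous_skewed", "kg/m^2", bounds=pos),
        V("hospital_stay", "continuous_skewed", "days", bounds=(0.0, np.inf)),
        V("etiology", "categorical", categories=ETIOLOGY_LEVELS),
        V("smoking", "binary"),
        V("av_fistula", "binary"),
        V("surgery_time", "continuous_normal", "minutes", bounds=(0.0, np.inf)),
        V("stent_number", "count", bounds=(1.0, np.inf)),
        V("stent_length_total", "continuous_normal", "mm", bounds=pos),
        V("stent_diameter", "continuous_normal", "mm", bounds=pos),
        V("ivc_extension", "continuous_skewed", "mm", bounds=pos),
        V("anticoagulation", "categorical", categories=ANTICOAG_LEVELS),
        V("compression", "binary"),
        V("pt", "continuous_normal", "s", bounds=(0.0, np.inf)),
        V("aptt", "continuous_normal", "s", bounds=(0.0, np.inf)),
        V("fib", "continuous_skewed", "g/L", bounds=(0.0, np.inf)),
        V("d_dimer", "continuous_skewed", "mg/L", bounds=(0.0, np.inf)),
        V("crp", "continuous_skewed", "mg/L", bounds=(0.0, np.inf)),
        V("eiv_recan", "continuous_normal", "%", bounds=pct),
        V("cfv_recan", "continuous_skewed", "%", bounds=pct),
        V("fv_recan", "continuous_skewed", "%", bounds=pct),
    ]


@dataclass
class CohortTable:
    """Schema-validated patient records with a binary occlusion outcome."""

    schema: list[VariableSchema]
    records: pd.DataFrame
    outcome: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = [v.name for v in self.schema]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        missing = [n for n in names if n not in self.records.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        unknown = [c for c in self.records.columns if c not in names and c != OUTCOME]
        if unknown:
            raise SchemaError(f"unknown columns not in schema: {unknown}")
        if self.outcome is None:
            if OUTCOME not in self.records.columns:
                raise SchemaError(f"no outcome column {OUTCOME!r} and no outcome vector")
            self.outcome = self.records[OUTCOME].to_numpy()
            self.records = self.records.drop(columns=[OUTCOME])
        self.outcome = np.asarray(self.outcome)
        if len(self.records) < 1:
            raise ValidationError("cohort must contain at least one record")
        if len(self.outcome) != len(self.records):
            raise ValidationError("outcome length does not match record count")
        if pd.isna(self.outcome).any():
            raise ValidationError("missing outcome values are not allowed")
        bad = set(np.unique(self.outcome)) - {0, 1}
        if bad:
            raise ValidationError(f"outcome must be binary 0/1, found {sorted(bad)}")
        self.outcome = self.outcome.astype(int)
        self.records = self.records[names].reset_index(drop=True)
        self._validate_values()

    def _validate_values(self) -> None:
        for var in self.schema:
            col = self.records[var.name]
            if col.isna().any():
                row = int(col.index[col.isna()][0]) + 1
                raise ValidationError(f"missing value in column {var.name!r}, row {row}")
            if var.kind == "categorical":
                known = set(var.categories)
                bad = col[~col.isin(known)]
                if len(bad):
                    row = int(bad.index[0]) + 1
                    raise ValidationError(
                        f"unknown category {bad.iloc[0]!r} in column {var.name!r}, row {row}"
                    )
                self.records[var.name] = pd.Categorical(col, categories=var.categories)
            elif var.kind == "binary":
                vals = set(pd.unique(col))
                if not vals <= {0, 1, 0.0, 1.0, True, False}:
                    raise ValidationError(f"column {var.name!r} must be 0/1")
                self.records[var.name] = col.astype(int)
            else:
                vals = pd.to_numeric(col, errors="coerce")
                if vals.isna().any():
                    row = int(vals.index[vals.isna()][0]) + 1
                    raise ValidationError(f"non-numeric value in {var.name!r}, row {row}")
                lo, hi = var.bounds
                out = vals[(vals < lo) | (vals > hi)]
                if len(out):
                    row = int(out.index[0]) + 1
                    raise ValidationError(
                        f"value {out.iloc[0]} out of range [{lo}, {hi}] "
                        f"in column {var.name!r}, row {row}"
                    )
                self.records[var.name] = vals.astype(float)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_events(self) -> int:
        return int(self.outcome.sum())

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    def subset(self, index: Sequence[int]) -> "CohortTable":
        idx = np.asarray(index, dtype=int)
        return CohortTable(self.schema, self.records.iloc[idx].reset_index(drop=True),
                           self.outcome[idx])

    def with_outcome_frame(self) -> pd.DataFrame:
        df = self.records.copy()
        df[OUTCOME] = self.outcome
        return df


def schema_to_json(schema: Sequence[VariableSchema], path: str | Path) -> None:
    payload = [
        {
            "name": v.name,
            "kind": v.kind,
            "units": v.units,
            "categories": list(v.categories),
            "bounds": [None if not np.isfinite(b) else b for b in v.bounds],
        }
        for v in schema
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def schema_from_json(path: str | Path) -> list[VariableSchema]:
    payload = json.loads(Path(path).read_text())
    out = []
    for item in payload:
        lo, hi = item.get("bounds", [None, None])
        out.append(
            VariableSchema(
                item["name"],
                item["kind"],
                item.get("units", ""),
                tuple(item.get("categories", [])),
                (-np.inf if lo is None else lo, np.inf if hi is None else hi),
            )
        )
    return out


def load_cohort(path: str | Path, schema: Sequence[VariableSchema]) -> CohortTable:
    """Read a cohort CSV (UTF-8, header row, '.' decimal) against a schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return CohortTable(list(schema), df)


def save_cohort(table: CohortTable, path: str | Path) -> None:
    table.with_outcome_frame().to_csv(path, index=False)
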