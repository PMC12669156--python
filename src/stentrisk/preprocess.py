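"""Train-frozen standardization and encoding.

Continuous and count variables are z-scored with training mean/sd, binary
variables pass through as {0,1}, and categorical variables are one-hot
encoded with the first schema level as reference. Parameters are fitted on
the training partition only and frozen for test-time reuse, so no
information from held-out rows leaks into the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import CohortTable, ValidationError


@dataclass
class PreprocessParams:
    feature_names: list[str]
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)
    source_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "means": self.means,
            "sds": self.sds,
            "categories": {k: list(v) for k, v in self.categories.items()},
            "source_columns": self.source_columns,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessParams":
        return cls(
            list(d["feature_names"]),
            {k: float(v) for k, v in d["means"].items()},
            {k: float(v) for k, v in d["sds"].items()},
            {k: tuple(v) for k, v in d["categories"].items()},
            list(d["source_columns"]),
        )


def fit_preprocess(train: CohortTable) -> PreprocessParams:
    params = PreprocessParams(feature_names=[])
    for var in train.schema:
        params.source_columns.append(var.name)
        col = train.records[var.name]
        if var.kind == "categorical":
            params.categories[var.name] = tuple(var.categories)
            # reference level = first schema category, indicators for the rest
            for level in var.categories[1:]:
                params.feature_names.append(f"{var.name}={level}")
        elif var.kind == "binary":
            params.feature_names.append(var.name)
        else:
            v = col.to_numpy(dtype=float)
            mu = float(v.mean())
            sd = float(v.std(ddof=0))
            params.means[var.name] = mu
            params.sds[var.name] = sd if sd > 0 else 1.0
            params.feature_names.append(var.name)
    return params


def apply_preprocess(params: PreprocessParams, table: CohortTable) -> np.ndarray:
    """Encode a table into the frozen numeric design matrix."""
    cols: list[np.ndarray] = []
    for var in table.schema:
        col = table.records[var.name]
        if var.name in params.categories:
            levels = params.categories[var.name]
            vals = col.astype(str)
            unseen = set(vals.unique()) - set(levels)
            if unseen:
                raise ValidationError(
                    f"unseen categories {sorted(unseen)} in column {var.name!r}"
                )
            for level in levels[1:]:
                cols.append((vals == level).to_numpy(dtype=float))
        elif var.name in params.means:
            v = col.to_numpy(dtype=float)
            cols.append((v - params.means[var.name]) / params.sds[var.name])
        else:
            cols.append(col.to_numpy(dtype=float))
    return np.column_stack(cols)


def design_frame(params: PreprocessParams, table: CohortTable) -> pd.DataFrame:
    return pd.DataFrame(apply_preprocess(params, table), columns=params.feature_names)
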