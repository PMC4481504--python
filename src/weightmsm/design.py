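"""Design-matrix construction shared by the exposure, censoring and outcome models.

All models in the pipeline are specified through :class:`CovariateSpec`, a plain
declaration of numeric columns and categorical columns with explicit level sets and
reference levels.  Building matrices through one code path keeps the numerator /
denominator nesting requirement of stabilized weighting checkable and guarantees that
a factor level that is absent from the data fails loudly instead of silently dropping
a column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SpecificationError


@dataclass(frozen=True)
class CovariateSpec:
    """Declarative covariate set: numeric columns plus categorical (levels, ref) pairs."""

    numeric: tuple[str, ...] = ()
    categorical: dict[str, tuple[tuple[str, ...], str]] = field(default_factory=dict)

    def columns(self) -> list[str]:
        return list(self.numeric) + list(self.categorical)

    def merge(self, other: "CovariateSpec") -> "CovariateSpec":
        cats = dict(self.categorical)
        cats.update(other.categorical)
        numeric = tuple(dict.fromkeys(self.numeric + other.numeric))
        return CovariateSpec(numeric=numeric, categorical=cats)

    def is_subset_of(self, other: "CovariateSpec") -> bool:
        return set(self.numeric) <= set(other.numeric) and set(
            self.categorical
        ) <= set(other.categorical)

    def drop(self, *cols: str) -> "CovariateSpec":
        return CovariateSpec(
            numeric=tuple(c for c in self.numeric if c not in cols),
            categorical={c: v for c, v in self.categorical.items() if c not in cols},
        )


def dummy_name(col: str, level: str) -> str:
    return f"{col}[{level}]"


def prune(spec: CovariateSpec, df: pd.DataFrame,
          keep: tuple[str, ...] = ()) -> CovariateSpec:
    """Drop covariates that are degenerate in ``df``: constant numerics and
    categoricals with a missing declared level.  Used for within-stratum refits,
    where stratum-constant covariates are inestimable by construction; columns in
    ``keep`` are never pruned (they fail loudly instead)."""
    numeric = tuple(
        c for c in spec.numeric
        if c in keep or (c in df.columns and df[c].nunique() > 1)
    )
    cats = {}
    for col, (levels, ref) in spec.categorical.items():
        if col in keep:
            cats[col] = (levels, ref)
            continue
        if col not in df.columns:
            continue
        observed = set(df[col].unique())
        if all(lv in observed for lv in levels) and len(observed) > 1:
            cats[col] = (levels, ref)
    return CovariateSpec(numeric=numeric, categorical=cats)


def dmatrix(df: pd.DataFrame, spec: CovariateSpec, const: bool = True,
            strict: bool = True) -> pd.DataFrame:
    """Build a dense design matrix for ``spec`` from ``df``.

    Raises :class:`SpecificationError` if a column is missing, contains NaN, holds a
    value outside the declared levels, or — when ``strict`` (the fitting path) — if
    a declared non-reference level never occurs (a level-deficient factor would
    otherwise yield a structurally zero, inestimable column).  Prediction on new
    rows uses ``strict=False``.
    """
    missing = [c for c in spec.columns() if c not in df.columns]
    if missing:
        raise SpecificationError(f"missing required columns: {missing}")
    blocks: list[pd.DataFrame] = []
    if const:
        blocks.append(pd.DataFrame({"const": np.ones(len(df))}, index=df.index))
    for col in spec.numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise SpecificationError(f"numeric covariate {col!r} contains missing values")
        blocks.append(vals.astype(float).to_frame(col))
    for col, (levels, ref) in spec.categorical.items():
        if ref not in levels:
            raise SpecificationError(f"reference {ref!r} not among levels of {col!r}")
        vals = df[col]
        if vals.isna().any():
            raise SpecificationError(f"categorical covariate {col!r} contains missing values")
        observed = set(vals.unique())
        unknown = observed - set(levels)
        if unknown:
            raise SpecificationError(f"covariate {col!r} has undeclared levels {sorted(unknown)}")
        deficient = [lv for lv in levels if lv != ref and lv not in observed]
        if deficient and strict:
            raise SpecificationError(
                f"factor {col!r} is level-deficient: no rows with level(s) {deficient}"
            )
        for lv in levels:
            if lv == ref:
                continue
            blocks.append(
                (vals == lv).astype(float).to_frame(dummy_name(col, lv))
            )
    return pd.concat(blocks, axis=1)
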