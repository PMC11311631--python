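"""Reading, validating, and encoding mixed-type cohort tables.

A clinical cohort is a subjects x features table in which each feature is
one of five kinds: continuous, ordinal, nominal, symmetric binary, or
asymmetric binary.  The schema travels with the data (as a JSON or YAML
sidecar) so that every downstream step -- Gower distances, numeric
encoding, dichotomization -- knows how to treat each column.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FTYPES",
    "BINARY_TYPES",
    "FeatureSchema",
    "MixedDataset",
    "SchemaError",
    "DataValidationError",
    "read_cohort",
    "write_cohort",
    "read_schema",
    "write_schema",
    "dichotomize_median",
    "to_numeric",
]

FTYPES = ("continuous", "ordinal", "nominal", "binary_symmetric", "binary_asymmetric")
BINARY_TYPES = ("binary_symmetric", "binary_asymmetric")

DEFAULT_NA_TOKENS = ("", "NA")


class SchemaError(ValueError):
    """A feature schema is malformed or inconsistent."""


class DataValidationError(ValueError):
    """A data value does not conform to its declared feature schema."""


@dataclass(frozen=True)
class FeatureSchema:
    """Declares how one column of the cohort table is to be interpreted.

    Parameters
    ----------
    name
        Column label in the table.
    ftype
        One of ``continuous``, ``ordinal``, ``nominal``, ``binary_symmetric``,
        ``binary_asymmetric``.
    levels
        Ordered category labels; required for every non-continuous type.
        For ordinal features the order is the total order of the scale.
    positive_level
        For asymmetric binary features only: the level that counts as
        "present".  Joint absence of an asymmetric trait carries no
        similarity information in the Gower distance.
    """

    name: str
    ftype: str
    levels: tuple[str, ...] | None = None
    positive_level: str | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FTYPES:
            raise SchemaError(
                f"feature {self.name!r}: unknown type {self.ftype!r}; "
                f"expected one of {FTYPES}"
            )
        if self.levels is not None:
            object.__setattr__(self, "levels", tuple(str(x) for x in self.levels))
        if self.ftype == "continuous":
            if self.levels:
                raise SchemaError(f"feature {self.name!r}: continuous features take no levels")
        else:
            if not self.levels:
                raise SchemaError(f"feature {self.name!r}: type {self.ftype} requires levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"feature {self.name!r}: duplicate levels")
            if self.ftype in BINARY_TYPES and len(self.levels) != 2:
                raise SchemaError(f"feature {self.name!r}: binary features need exactly 2 levels")
        if self.ftype == "binary_asymmetric":
            if self.positive_level is None:
                raise SchemaError(f"feature {self.name!r}: asymmetric binary requires positive_level")
            if self.positive_level not in (self.levels or ()):
                raise SchemaError(
                    f"feature {self.name!r}: positive_level {self.positive_level!r} "
                    f"not among levels {self.levels}"
                )
        elif self.positive_level is not None:
            raise SchemaError(
                f"feature {self.name!r}: positive_level is only meaningful for binary_asymmetric"
            )

    @property
    def is_binary(self) -> bool:
        return self.ftype in BINARY_TYPES

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "ftype": self.ftype}
        if self.levels is not None:
            d["levels"] = list(self.levels)
        if self.positive_level is not None:
            d["positive_level"] = self.positive_level
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        extra = set(d) - {"name", "ftype", "levels", "positive_level"}
        if extra:
            raise SchemaError(f"unknown schema keys {sorted(extra)} for feature {d.get('name')!r}")
        levels = d.get("levels")
        return cls(
            name=str(d["name"]),
            ftype=str(d["ftype"]),
            levels=tuple(levels) if levels is not None else None,
            positive_level=d.get("positive_level"),
        )


@dataclass
class MixedDataset:
    """A validated subjects x features table with per-feature type annotations.

    ``values`` holds continuous columns as float64 (NaN = missing) and
    categorical columns as object/str (NaN = missing), indexed by subject ID.
    """

    schema: list[FeatureSchema]
    values: pd.DataFrame
    name: str = "cohort"
    _by_name: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.schema) != self.values.shape[1]:
            raise DataValidationError("schema length does not match number of columns")
        names = [f.name for f in self.schema]
        if list(self.values.columns) != names:
            raise DataValidationError("column order does not match schema order")
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names")
        if self.values.index.has_duplicates:
            raise DataValidationError("duplicate subject IDs")
        if self.n_subjects < 2 or self.n_features < 1:
            raise DataValidationError("need at least 2 subjects and 1 feature")
        self._by_name = {f.name: f for f in self.schema}
        self._validate_values()

    def _validate_values(self) -> None:
        for f in self.schema:
            col = self.values[f.name]
            if f.ftype == "continuous":
                if not np.issubdtype(col.dtype, np.floating):
                    try:
                        self.values[f.name] = col.astype(float)
                    except (TypeError, ValueError) as exc:
                        raise DataValidationError(
                            f"feature {f.name!r}: non-numeric value in continuous column"
                        ) from exc
            else:
                ok = col.isna() | col.astype("object").isin(f.levels)
                if not ok.all():
                    row = self.values.index[~ok][0]
                    bad = col[~ok].iloc[0]
                    raise DataValidationError(
                        f"value {bad!r} at row {row!r}, column {f.name!r} "
                        f"is not among declared levels {f.levels}"
                    )

    # -- basic introspection -------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.schema]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature(self, name: str) -> FeatureSchema:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no feature named {name!r}") from None

    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def binary_features(self) -> list[str]:
        return [f.name for f in self.schema if f.is_binary]

    def equals(self, other: "MixedDataset") -> bool:
        if self.schema != other.schema or self.subjects != other.subjects:
            return False
        a, b = self.values, other.values
        for f in self.schema:
            ca, cb = a[f.name], b[f.name]
            if not (ca.isna() == cb.isna()).all():
                return False
            if f.ftype == "continuous":
                if not np.allclose(ca.dropna(), cb.dropna(), rtol=0, atol=1e-12):
                    return False
            elif not (ca.dropna() == cb.dropna()).all():
                return False
        return True


# ---------------------------------------------------------------------------
# schema and table I/O


def read_schema(schema_path: str | Path) -> list[FeatureSchema]:
    """Load a feature schema from a JSON or YAML document.

    The document is either a list of feature mappings or a mapping with a
    top-level ``features`` key holding that list.
    """
    path = Path(schema_path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if isinstance(doc, dict):
        doc = doc.get("features")
    if not isinstance(doc, list):
        raise SchemaError(f"{path}: expected a list of feature entries")
    return [FeatureSchema.from_dict(d) for d in doc]


def write_schema(schema: Sequence[FeatureSchema], schema_path: str | Path) -> None:
    path = Path(schema_path)
    doc = {"features": [f.to_dict() for f in schema]}
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2))


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_cohort(
    table_path: str | Path,
    schema_path: str | Path,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
) -> MixedDataset:
    """Read a delimited cohort table plus its schema into a :class:`MixedDataset`.

    The first column of the table holds subject IDs.  Every remaining column
    must be declared in the schema (unlisted columns are an error).  Cells
    equal to any of ``na_tokens`` map to missing.
    """
    table_path = Path(table_path)
    schema = read_schema(schema_path)
    raw = pd.read_csv(
        table_path, sep=_infer_sep(table_path), dtype=str,
        keep_default_na=False, index_col=0,
    )
    na = set(na_tokens)
    declared = [f.name for f in schema]
    unlisted = [c for c in raw.columns if c not in declared]
    if unlisted:
        raise SchemaError(f"{table_path}: columns {unlisted} not declared in schema")
    absent = [c for c in declared if c not in raw.columns]
    if absent:
        raise SchemaError(f"{table_path}: schema features {absent} missing from table")
    raw = raw[declared]

    cols = {}
    for f in schema:
        col = raw[f.name].map(lambda v: np.nan if v in na else v)
        if f.ftype == "continuous":
            try:
                col = col.astype(float)
            except (TypeError, ValueError) as exc:
                bad = next(v for v in col if isinstance(v, str))
                raise DataValidationError(
                    f"feature {f.name!r}: cannot parse {bad!r} as a real number"
                ) from exc
        cols[f.name] = col
    values = pd.DataFrame(cols, index=raw.index)[declared]
    return MixedDataset(schema=list(schema), values=values, name=table_path.stem)


def write_cohort(
    ds: MixedDataset,
    table_path: str | Path,
    schema_path: str | Path | None = None,
    na_token: str = "NA",
) -> None:
    """Canonical CSV/TSV writer; inverse of :func:`read_cohort`."""
    table_path = Path(table_path)
    out = ds.values.copy()
    out.index.name = out.index.name or "subject"
    out.to_csv(table_path, sep=_infer_sep(table_path), na_rep=na_token)
    if schema_path is not None:
        write_schema(ds.schema, schema_path)


# ---------------------------------------------------------------------------
# transformations


def dichotomize_median(ds: MixedDataset, feature: str) -> MixedDataset:
    """Split a continuous feature at its median into Low/High.

    Values less than or equal to the median of the non-missing values become
    ``"Low"``; values above become ``"High"``.  The boundary lands in the
    low group, matching the clinical cutoff convention (e.g. B2M <= 4 mg/L
    counting as Low).  Missing entries stay missing.
    """
    f = ds.feature(feature)
    if f.ftype != "continuous":
        raise ValueError(f"feature {feature!r} is {f.ftype}, not continuous")
    col = ds.values[feature]
    nonmiss = col.dropna()
    if nonmiss.empty:
        raise ValueError(f"feature {feature!r} has no non-missing values")
    med = float(nonmiss.median())
    newcol = col.map(lambda v: np.nan if pd.isna(v) else ("Low" if v <= med else "High"))
    newf = FeatureSchema(name=feature, ftype="binary_symmetric", levels=("Low", "High"))
    schema = [newf if g.name == feature else g for g in ds.schema]
    values = ds.values.copy()
    values[feature] = newcol
    return MixedDataset(schema=schema, values=values, name=ds.name)


def to_numeric(ds: MixedDataset) -> pd.DataFrame:
    """Encode every feature as a float column (NaN = missing).

    Binary features map to {0, 1} in level order, except that for asymmetric
    binary features the declared positive level maps to 1.  Ordinal features
    map to rank codes 0..k-1.  Nominal features with more than two levels map
    to integer codes in level order; these codes are unordered labels, usable
    for sector averaging but not for distances.  Continuous features pass
    through unchanged.
    """
    cols = {}
    for f in ds.schema:
        col = ds.values[f.name]
        if f.ftype == "continuous":
            cols[f.name] = col.astype(float)
            continue
        levels = list(f.levels)
        if f.ftype == "binary_asymmetric" and f.positive_level != levels[1]:
            levels = [lv for lv in levels if lv != f.positive_level] + [f.positive_level]
        code = {lv: float(i) for i, lv in enumerate(levels)}
        cols[f.name] = col.map(lambda v: np.nan if pd.isna(v) else code[v]).astype(float)
    return pd.DataFrame(cols, index=ds.values.index)[ds.feature_names]
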