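"""Core data containers: column schemas, raw patient records, feature matrices,
and CSV round-trip I/O.

A raw record holds one patient's untransformed fields.  Numeric fields are
floats; binary fields hold one of two text tokens (e.g. ``"no"``/``"yes"``);
degree-graded fields hold either an absence token (e.g. ``"none"``) or one of
an ordered list of severity terms (e.g. ``"mild" < "moderate" < "severe"``).
A missing field is ``None`` in memory and an empty cell in CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, ParseError, SchemaError

SCHEME_COLUMN = "scheme"
COST_COLUMN = "cost"

KINDS = ("numeric", "binary", "degree")


@dataclass(frozen=True)
class ColumnSpec:
    """Declaration of one feature column.

    Parameters
    ----------
    name : str
        Column identifier.
    kind : {"numeric", "binary", "degree"}
        Statistical kind of the column.
    levels : sequence of str, optional
        For ``degree`` columns, the severity vocabulary in rank order;
        the patient's level ``x`` is the 1-based index into this list and
        ``a = len(levels)`` is the total number of levels.
    absent : str
        For ``degree`` columns, the token meaning the symptom is absent
        (distinct from a missing cell, which means the information was
        never recorded).
    tokens : (str, str)
        For ``binary`` columns, the (negative, positive) text tokens.
    """

    name: str
    kind: str
    levels: Optional[tuple] = None
    absent: str = "none"
    tokens: tuple = ("no", "yes")

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigError(f"column {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "degree":
            if not self.levels:
                raise ConfigError(f"column {self.name!r}: degree column needs levels")
            object.__setattr__(self, "levels", tuple(self.levels))
        if self.kind == "binary":
            object.__setattr__(self, "tokens", tuple(self.tokens))

    @property
    def a(self) -> int:
        """Number of severity levels of a degree column."""
        if self.kind != "degree":
            raise AttributeError(f"column {self.name!r} is not a degree column")
        return len(self.levels)


@dataclass(frozen=True)
class Schema:
    """Ordered collection of feature columns plus the scheme label set."""

    columns: tuple
    scheme_labels: Optional[tuple] = None

    def __post_init__(self):
        object.__setattr__(self, "columns", tuple(self.columns))
        if self.scheme_labels is not None:
            object.__setattr__(self, "scheme_labels", tuple(self.scheme_labels))
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise ConfigError("schema: duplicate column names")
        for reserved in (SCHEME_COLUMN, COST_COLUMN):
            if reserved in names:
                raise ConfigError(f"schema: column name {reserved!r} is reserved")

    @property
    def names(self) -> list:
        return [c.name for c in self.columns]

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"unknown column {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(c.name == name for c in self.columns)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        cols = []
        for c in self.columns:
            d = {"name": c.name, "kind": c.kind}
            if c.kind == "degree":
                d["levels"] = list(c.levels)
                d["absent"] = c.absent
            elif c.kind == "binary":
                d["tokens"] = list(c.tokens)
            cols.append(d)
        out = {"columns": cols}
        if self.scheme_labels is not None:
            out["scheme_labels"] = list(self.scheme_labels)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "Schema":
        cols = []
        for c in d["columns"]:
            cols.append(
                ColumnSpec(
                    name=c["name"],
                    kind=c["kind"],
                    levels=tuple(c["levels"]) if "levels" in c else None,
                    absent=c.get("absent", "none"),
                    tokens=tuple(c.get("tokens", ("no", "yes"))),
                )
            )
        labels = d.get("scheme_labels")
        return cls(columns=tuple(cols), scheme_labels=tuple(labels) if labels else None)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "Schema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RawRecord:
    """One patient's untransformed fields.

    ``fields`` maps feature name to raw value (float, text token, or None
    when missing); ``scheme`` is the treatment-scheme label if known; ``cost``
    is the continuous target if known.
    """

    fields: dict
    scheme: Optional[str] = None
    cost: Optional[float] = None

    def copy(self) -> "RawRecord":
        return RawRecord(dict(self.fields), self.scheme, self.cost)


@dataclass
class FeatureMatrix:
    """Fully numeric n x p design plus per-column metadata and targets.

    ``X`` is float-valued with NaN marking missing cells; ``columns`` carries
    each feature's kind (and level count for degree features); ``scheme`` and
    ``cost`` align with ``X``'s rows and may contain missing entries.
    """

    X: pd.DataFrame
    columns: tuple
    scheme: Optional[pd.Series] = None
    cost: Optional[pd.Series] = None

    @property
    def n_records(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X.copy(),
            self.columns,
            None if self.scheme is None else self.scheme.copy(),
            None if self.cost is None else self.cost.copy(),
        )

    def column_spec(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"unknown column {name!r}")


# ---------------------------------------------------------------------------
# CSV I/O.  Missing-value marker is the empty string; header row mandatory.
# ---------------------------------------------------------------------------


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_records(records: Sequence[RawRecord], path, schema: Schema) -> None:
    """Write records to CSV: one row per patient, columns = features + scheme
    + cost, empty cells for missing values.  Floats are written with full
    precision so that a read/write round trip is lossless."""
    names = schema.names
    rows = []
    for r in records:
        row = [_format_cell(r.fields.get(n)) for n in names]
        row.append(_format_cell(r.scheme))
        row.append(_format_cell(r.cost))
        rows.append(row)
    df = pd.DataFrame(rows, columns=names + [SCHEME_COLUMN, COST_COLUMN])
    df.to_csv(path, index=False)


def _parse_cell(text: str, spec: ColumnSpec, lineno: int):
    if text == "":
        return None
    if spec.kind == "numeric":
        try:
            return float(text)
        except ValueError:
            raise ParseError(
                f"line {lineno}: column {spec.name!r}: {text!r} is not numeric"
            ) from None
    return text


def read_records(path, schema: Schema):
    """Read a records CSV written by :func:`write_records`.

    Returns a list of :class:`RawRecord`.  Raises :class:`ParseError` with a
    line number on a malformed row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = schema.names + [SCHEME_COLUMN, COST_COLUMN]
    missing_cols = [c for c in expected if c not in df.columns]
    if missing_cols:
        raise ParseError(f"line 1: missing columns {missing_cols}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        row = dict(zip(df.columns, row))
        fields = {n: _parse_cell(row[n], schema[n], lineno) for n in schema.names}
        scheme = row[SCHEME_COLUMN] or None
        cost_text = row[COST_COLUMN]
        if cost_text == "":
            cost = None
        else:
            try:
                cost = float(cost_text)
            except ValueError:
                raise ParseError(
                    f"line {lineno}: column 'cost': {cost_text!r} is not numeric"
                ) from None
        records.append(RawRecord(fields=fields, scheme=scheme, cost=cost))
    return records


def records_to_frame(records: Sequence[RawRecord], schema: Schema) -> pd.DataFrame:
    """Raw records as an object-dtype DataFrame (None for missing)."""
    data = {n: [r.fields.get(n) for r in records] for n in schema.names}
    data[SCHEME_COLUMN] = [r.scheme for r in records]
    data[COST_COLUMN] = [r.cost for r in records]
    return pd.DataFrame(data)
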