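"""Digitization of text-valued EMR descriptors.

Two kinds of descriptive variables occur in the records.  A *qualitative*
descriptor (smoking, abdominal pain, ...) is present or absent and maps to
{0, 1}.  A *degree* descriptor carries an ordinal severity with ``a`` levels;
a patient at level ``x`` (1-based) maps to

    y = 0            if the symptom is absent (b = 0)
    y = 0.5 + x/(2a) if present (b != 0)

so absence scores 0, presence contributes a base value of 0.5, and severity
adds x/(2a), giving an image of {0} | (0.5, 1] with exactly a + 1 distinct
values.  Maximum severity (x = a) maps to exactly 1 for every a.  The
transform is linear in x, so the ordinal spacing of the severity grades is
preserved and the output stays discrete.

A missing text field is *not* an absent symptom: absence of the symptom is
information (b = 0) whereas a blank cell is absence of information, and the
two must reach the imputer differently.  Digitization therefore propagates
missing fields as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, VocabularyError
from .records import (
    COST_COLUMN,
    SCHEME_COLUMN,
    ColumnSpec,
    FeatureMatrix,
    RawRecord,
    Schema,
)


@dataclass(frozen=True)
class DegreeDescriptor:
    """A (symptom, severity) observation: ``a`` total levels, patient level
    ``x`` (0 when absent), presence flag ``b`` (0 = absent)."""

    name: str
    a: int
    x: int
    b: int


def digitize_degree(a: int, b: int, x: int) -> float:
    """Numeric value of a degree descriptor.

    Parameters
    ----------
    a : int
        Total number of severity levels (>= 1).
    b : int
        Presence flag; 0 means the symptom is absent.
    x : int
        The patient's severity level, 1..a when present, 0 when absent.

    Returns
    -------
    float
        0 when absent, else ``0.5 + x / (2 a)``.
    """
    if a < 1:
        raise DomainError(f"a must be >= 1, got {a}")
    if x < 0 or x > a:
        raise DomainError(f"x must be in [0, {a}], got {x}")
    if b == 0:
        if x != 0:
            raise DomainError(f"absent symptom (b=0) must have x=0, got x={x}")
        return 0.0
    if x == 0:
        raise DomainError("present symptom (b!=0) must have level x >= 1")
    return 0.5 + x / (2 * a)


def digitize_qualitative(present: bool) -> float:
    """Numeric value of a present/absent descriptor: 1.0 or 0.0."""
    return 1.0 if present else 0.0


def degree_grid(a: int) -> np.ndarray:
    """The full image of the degree transform for ``a`` levels:
    {0} plus 0.5 + x/(2a) for x = 1..a (a + 1 values)."""
    return np.concatenate([[0.0], 0.5 + np.arange(1, a + 1) / (2 * a)])


def _digitize_cell(value, spec: ColumnSpec) -> float:
    """One raw cell -> float (NaN for missing)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if spec.kind == "numeric":
        return float(value)
    if spec.kind == "binary":
        if value == spec.tokens[1]:
            return digitize_qualitative(True)
        if value == spec.tokens[0]:
            return digitize_qualitative(False)
        raise VocabularyError(
            f"column {spec.name!r}: unrecognized token {value!r} "
            f"(expected one of {list(spec.tokens)})"
        )
    # degree
    if value == spec.absent:
        return digitize_degree(spec.a, b=0, x=0)
    try:
        x = spec.levels.index(value) + 1
    except ValueError:
        raise VocabularyError(
            f"column {spec.name!r}: unrecognized severity term {value!r} "
            f"(expected {spec.absent!r} or one of {list(spec.levels)})"
        ) from None
    return digitize_degree(spec.a, b=1, x=x)


def digitize_table(records: Sequence[RawRecord], schema: Schema) -> FeatureMatrix:
    """Digitize a list of raw records into a fully numeric feature matrix.

    Numeric columns pass through unchanged; binary and degree columns are
    converted cell-wise.  Missing fields become NaN (never 0).  Unknown
    columns in a record raise :class:`SchemaError`; unknown vocabulary raises
    :class:`VocabularyError` naming the term.
    """
    names = schema.names
    known = set(names) | {SCHEME_COLUMN, COST_COLUMN}
    data = np.full((len(records), len(names)), np.nan)
    schemes = []
    costs = []
    for i, rec in enumerate(records):
        extra = set(rec.fields) - known
        if extra:
            raise SchemaError(f"record {i}: unknown column(s) {sorted(extra)}")
        for j, name in enumerate(names):
            data[i, j] = _digitize_cell(rec.fields.get(name), schema[name])
        schemes.append(rec.scheme)
        costs.append(np.nan if rec.cost is None else float(rec.cost))
    X = pd.DataFrame(data, columns=names)
    scheme = pd.Series(schemes, dtype=object, name=SCHEME_COLUMN)
    cost = pd.Series(costs, dtype=float, name=COST_COLUMN)
    return FeatureMatrix(X=X, columns=schema.columns, scheme=scheme, cost=cost)
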