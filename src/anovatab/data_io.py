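"""Reading and validating two-factor long-format tables.

A dataset is a long-format table with exactly two text-valued factor columns
and one or more numeric response columns.  A column is treated as a factor as
soon as at least one of its values fails numeric parsing; purely numeric
columns are responses even when integer-coded, which is why factor levels
must be spelled with letters ("HF"/"LF", not 0/1).

Column names are sanitized to valid identifiers (letters, digits, dot,
underscore; leading letter or dot-not-followed-by-a-digit).  Factor *level
values* are kept verbatim so that the digit-prefix ordering trick
("1Overweight" < "2Lean") works without special casing.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import (
    DesignError,
    InputError,
    SchemaError,
    SheetNotFoundError,
)

log = logging.getLogger("anovatab")

__all__ = [
    "Dataset",
    "Schema",
    "read_dataset",
    "read_workbook",
    "sanitize_name",
    "infer_schema",
    "order_levels",
]


# --------------------------------------------------------------------------
# name hygiene

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "π": "pi", "ρ": "rho",
    "σ": "sigma", "τ": "tau", "υ": "upsilon", "φ": "phi", "χ": "chi",
    "ψ": "psi", "ω": "omega",
    "Α": "Alpha", "Β": "Beta", "Γ": "Gamma", "Δ": "Delta", "Ε": "Epsilon",
    "Ζ": "Zeta", "Η": "Eta", "Θ": "Theta", "Ι": "Iota", "Κ": "Kappa",
    "Λ": "Lambda", "Μ": "Mu", "Ν": "Nu", "Ξ": "Xi", "Π": "Pi", "Ρ": "Rho",
    "Σ": "Sigma", "Τ": "Tau", "Υ": "Upsilon", "Φ": "Phi", "Χ": "Chi",
    "Ψ": "Psi", "Ω": "Omega",
}

_VALID_NAME = re.compile(r"^(?:[A-Za-z]|\.(?![0-9]))[A-Za-z0-9._]*$")


def sanitize_name(raw: object) -> str:
    """Return a valid identifier derived deterministically from *raw*.

    Spaces become underscores, Greek letters are transliterated to their
    ASCII names, any other invalid character becomes a dot, and names that
    start with a digit or with a dot followed by a digit are prefixed with
    "X" (so ".2Ala" -> "X.2Ala").  Idempotent.
    """
    text = str(raw).strip()
    if not text:
        raise InputError("cannot sanitize an empty name")
    text = "".join(_GREEK.get(ch, ch) for ch in text)
    text = text.replace(" ", "_")
    text = re.sub(r"[^A-Za-z0-9._]", ".", text)
    if not _VALID_NAME.match(text):
        text = "X" + text
    if raw != text:
        log.info("sanitized name %r -> %r", raw, text)
    return text


def order_levels(levels: Iterable[str]) -> list[str]:
    """Order factor levels lexicographically by code point.

    This is the ordering used for the output table columns; prefixing levels
    with digits ("1Overweight", "2Lean") overrides the alphabetical default.
    """
    out = sorted(set(levels))
    if len(out) < 2:
        raise DesignError(
            f"a factor must have at least two distinct levels, got {out!r}"
        )
    return out


# --------------------------------------------------------------------------
# schema inference

class _Text:
    """Sentinel: the value is text, i.e. not parseable as a number."""


_TEXT = _Text()


def _parse_cell(value: object):
    """Missing -> None, number-like -> float, anything else -> _TEXT."""
    if value is None:
        return None
    if isinstance(value, bool):
        return _TEXT
    if isinstance(value, (int, float, np.integer, np.floating)):
        return None if (isinstance(value, float) and math.isnan(value)) else float(value)
    text = str(value).strip()
    if not text:
        return None
    try:
        return float(text)
    except ValueError:
        return _TEXT


@dataclass(frozen=True)
class Schema:
    """Column roles and level orderings inferred from a raw table."""

    factor_columns: tuple[str, str]
    response_columns: tuple[str, ...]
    level_order_a: tuple[str, ...]
    level_order_b: tuple[str, ...]


def infer_schema(raw_table: pd.DataFrame) -> Schema:
    """Classify columns of a header-named grid into factors and responses.

    A column is a factor iff at least one non-missing value fails numeric
    parsing; exactly two factor columns are required (in order of
    appearance) and at least one numeric response column.
    """
    if raw_table.shape[1] < 3 or raw_table.shape[0] < 1:
        raise SchemaError(
            "a dataset needs at least two factor columns and one response "
            f"column with at least one data row; got shape {raw_table.shape}"
        )
    factors: list[str] = []
    responses: list[str] = []
    for col in raw_table.columns:
        parsed = [_parse_cell(v) for v in raw_table[col]]
        if any(v is _TEXT for v in parsed):
            factors.append(str(col))
        else:
            responses.append(str(col))
    if len(factors) != 2:
        raise SchemaError(
            f"unable to find two factors: found {len(factors)} text-valued "
            f"column(s) {factors!r} (factor levels must be described using "
            "letters, not numbers)"
        )
    if not responses:
        raise SchemaError("no numeric response columns found")

    def _levels(col: str) -> tuple[str, ...]:
        vals = [str(v).strip() for v in raw_table[col]
                if _parse_cell(v) is not None]
        return tuple(order_levels(vals))

    return Schema(
        factor_columns=(factors[0], factors[1]),
        response_columns=tuple(responses),
        level_order_a=_levels(factors[0]),
        level_order_b=_levels(factors[1]),
    )


# --------------------------------------------------------------------------
# the dataset container

Responses = Mapping[str, Optional[float]]


@dataclass
class Dataset:
    """A validated two-factor long-format dataset.

    records holds one (level_a, level_b, responses) triple per table row;
    missing numeric values are None, missing factor labels are an error.
    """

    factor_a_name: str
    factor_b_name: str
    records: list[tuple[str, str, dict[str, Optional[float]]]]
    source_sheet: str = "data"

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError(f"sheet {self.source_sheet!r}: no data rows")
        names = tuple(self.records[0][2])
        for la, lb, resp in self.records:
            if not la or not lb:
                raise SchemaError(
                    f"sheet {self.source_sheet!r}: missing factor label"
                )
            if tuple(resp) != names:
                raise SchemaError(
                    f"sheet {self.source_sheet!r}: inconsistent response "
                    "columns across rows"
                )
        # each factor must actually vary
        order_levels(r[0] for r in self.records)
        order_levels(r[1] for r in self.records)

    @property
    def response_names(self) -> list[str]:
        return list(self.records[0][2])

    @property
    def levels_a(self) -> list[str]:
        return order_levels(r[0] for r in self.records)

    @property
    def levels_b(self) -> list[str]:
        return order_levels(r[1] for r in self.records)

    @property
    def treatments(self) -> list[tuple[str, str]]:
        """All level combinations in (A-order x B-order) sequence."""
        return [(la, lb) for la in self.levels_a for lb in self.levels_b]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {self.factor_a_name: la, self.factor_b_name: lb, **resp}
            for la, lb, resp in self.records
        ]
        return pd.DataFrame(
            rows,
            columns=[self.factor_a_name, self.factor_b_name]
            + self.response_names,
        )


def _dataset_from_frame(frame: pd.DataFrame, sheet: str) -> Dataset:
    frame = frame.dropna(axis=0, how="all").dropna(axis=1, how="all")
    if frame.empty or frame.shape[1] == 0:
        raise InputError(f"sheet {sheet!r} is empty")
    renames = {c: sanitize_name(c) for c in frame.columns}
    if len(set(renames.values())) != len(renames):
        raise SchemaError(
            f"sheet {sheet!r}: column names collide after sanitization"
        )
    frame = frame.rename(columns=renames)
    try:
        schema = infer_schema(frame)
    except SchemaError as exc:
        raise SchemaError(f"sheet {sheet!r}: {exc}") from exc
    fa, fb = schema.factor_columns
    records = []
    for idx, row in frame.iterrows():
        resp: dict[str, Optional[float]] = {}
        for col in schema.response_columns:
            resp[col] = _parse_cell(row[col])
        for col in (fa, fb):
            if _parse_cell(row[col]) is None:
                raise SchemaError(
                    f"sheet {sheet!r}: missing {col!r} label in row {idx}"
                )
        records.append((str(row[fa]).strip(), str(row[fb]).strip(), resp))
    return Dataset(fa, fb, records, source_sheet=sheet)


# --------------------------------------------------------------------------
# file reading

def _open_workbook(path: Path) -> pd.ExcelFile:
    if path.suffix.lower() == ".xls":
        raise InputError(
            "legacy .xls workbooks are not supported in this build "
            "(no xlrd engine available); convert to .xlsx or .csv"
        )
    try:
        return pd.ExcelFile(path, engine="openpyxl")
    except Exception as exc:  # corrupt / not-a-workbook
        raise InputError(f"cannot read workbook {path}: {exc}") from exc


def read_dataset(
    source: Union[str, Path], sheet: Union[str, int, None] = None
) -> Dataset:
    """Read one dataset from a workbook sheet (or a CSV file).

    *sheet* may be a name, a 0-based index, or None for the first sheet.
    """
    path = Path(source)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() == ".csv":
        try:
            frame = pd.read_csv(path)
        except Exception as exc:
            raise InputError(f"cannot read CSV {path}: {exc}") from exc
        return _dataset_from_frame(frame, path.stem)
    book = _open_workbook(path)
    names = book.sheet_names
    if sheet is None:
        name = names[0]
    elif isinstance(sheet, int):
        try:
            name = names[sheet]
        except IndexError:
            raise SheetNotFoundError(
                f"workbook {path} has {len(names)} sheet(s); index {sheet} "
                "out of range"
            ) from None
    else:
        if sheet not in names:
            raise SheetNotFoundError(
                f"no sheet {sheet!r} in workbook {path} (sheets: {names})"
            )
        name = sheet
    frame = book.parse(name, header=0)
    return _dataset_from_frame(frame, name)


def read_workbook(source: Union[str, Path]) -> list[Dataset]:
    """Read every non-empty sheet of a workbook, in sheet order.

    Any sheet that fails validation aborts the read with an error naming
    the sheet.  A CSV file yields a singleton list.
    """
    path = Path(source)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() == ".csv":
        return [read_dataset(path)]
    book = _open_workbook(path)
    datasets: list[Dataset] = []
    for name in book.sheet_names:
        frame = book.parse(name, header=0)
        if frame.dropna(axis=0, how="all").dropna(axis=1, how="all").empty:
            log.info("skipping empty sheet %r", name)
            continue
        datasets.append(_dataset_from_frame(frame, name))
    if not datasets:
        raise InputError(f"workbook {path} contains no non-empty sheets")
    return datasets
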