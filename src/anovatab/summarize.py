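"""Numeric formatting, pooled SEM and table assembly.

Two table layouts are produced: "per-group SEM" rows show mean ± SEM for
every treatment with superscript letters, while "pooled SEM" rows show the
means only plus a single pooled standard error column.  The last three
columns always carry the two-way p-values (factor A, factor B,
interaction), and a caption describing the summary, the sample sizes, the
post-hoc test and the interaction abbreviation is generated automatically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Mapping, Optional, Sequence

import numpy as np

from .anova_core import AnovaResult, CellMeansFit, CellSummary
from .data_io import Dataset
from .exceptions import InputError
from .letters import LetterDisplay

__all__ = [
    "TableOptions",
    "ResponseResults",
    "CellDisplay",
    "TableRow",
    "SummaryTable",
    "pooled_sem",
    "format_sigfigs",
    "format_pvalue",
    "trim_trailing_zeros",
    "build_table",
    "build_caption",
]

FORMATS = ("per_group_sem", "pooled_sem")


@dataclass(frozen=True)
class TableOptions:
    """User-facing table knobs with the program's defaults."""

    alpha: float = 0.05
    sig_digits: int = 3      # significant digits for means and SEMs
    p_decimals: int = 3      # decimal places for p-values
    format: str = "per_group_sem"
    phc: bool = True         # include post-hoc letter superscripts
    test: str = "tukey"

    def __post_init__(self) -> None:
        if self.format not in FORMATS:
            raise InputError(f"format must be one of {FORMATS}")
        if self.sig_digits < 1 or self.p_decimals < 1:
            raise InputError("sig_digits and p_decimals must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InputError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ResponseResults:
    """Everything computed for one response, consumed by build_table."""

    cells: Sequence[CellSummary]
    anova: AnovaResult
    letters: Optional[LetterDisplay] = None
    pooled: Optional[float] = None


@dataclass(frozen=True)
class CellDisplay:
    text: str
    superscript: str = ""


@dataclass(frozen=True)
class TableRow:
    response: str
    cells: tuple[CellDisplay, ...]
    pooled: Optional[str]
    p_values: tuple[str, str, str]


@dataclass(frozen=True)
class SummaryTable:
    title: str
    factor_a: str
    factor_b: str
    levels_a: tuple[str, ...]
    levels_b: tuple[str, ...]
    pooled: bool
    p_headers: tuple[str, str, str]
    rows: tuple[TableRow, ...]
    caption: str

    @property
    def n_columns(self) -> int:
        return 1 + len(self.levels_a) * len(self.levels_b) \
            + (1 if self.pooled else 0) + 3


# --------------------------------------------------------------------------
# pooled SEM

def pooled_sem(fit: CellMeansFit) -> float:
    """Single table-wide standard error for comparing treatment means.

    Balanced designs: sqrt(MSE * 2/n).  Unbalanced designs: the pairwise
    pooled SEM sqrt(MSE * (1/n_i + 1/n_j)) is computed for every pair and
    the highest one is reported.
    """
    if fit.balanced:
        n = fit.cells[0].n
        return float(np.sqrt(fit.mse * 2.0 / n))
    return max(
        float(np.sqrt(fit.mse * (1.0 / c1.n + 1.0 / c2.n)))
        for c1, c2 in itertools.combinations(fit.cells, 2)
    )


# --------------------------------------------------------------------------
# number formatting

def format_sigfigs(x: float, k: int) -> str:
    """Render *x* with exactly *k* significant digits.

    Zeros to the right of the decimal point and of the last non-zero digit
    are kept ("3.2" at k=5 is "3.2000"), but integers are not padded with
    decimal zeros ("359.4" at k=3 is "359").
    """
    if k < 1:
        raise InputError("need at least one significant digit")
    if not math.isfinite(x):
        raise InputError(f"cannot format non-finite value {x!r}")
    if x == 0:
        return "0"
    rounded = Decimal(f"{x:.{k - 1}e}")   # half-even at the k-th digit
    decimals = (k - 1) - rounded.adjusted()
    if decimals <= 0:
        return str(rounded.quantize(Decimal(1)))
    return str(rounded.quantize(Decimal(1).scaleb(-decimals)))


def trim_trailing_zeros(text: str) -> str:
    """Drop trailing fractional zeros from a rendered number ("4.20"->"4.2")."""
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text


def format_pvalue(p: float, d: int) -> str:
    """Render a p-value with *d* decimal places.

    Values below 10^-d are shown as "<0.001"-style bounds so that a
    positive p never renders as plain zero; otherwise round to d decimals
    and trim trailing zeros ("0.830" -> "0.83", "1.000" -> "1")."""
    if d < 1:
        raise InputError("need at least one decimal place")
    if not 0.0 <= p <= 1.0:
        raise InputError(f"p-value out of range: {p!r}")
    threshold = 10.0 ** (-d)
    if p < threshold:
        return "<" + f"{threshold:.{d}f}"
    return trim_trailing_zeros(f"{p:.{d}f}")


def _fmt(x: float, k: int) -> str:
    return trim_trailing_zeros(format_sigfigs(x, k))


# --------------------------------------------------------------------------
# table assembly

def _interaction_abbrev(factor_a: str, factor_b: str) -> str:
    return f"{factor_a[0]} × {factor_b[0]}"


def build_table(
    dataset: Dataset,
    results: Mapping[str, ResponseResults],
    options: TableOptions,
    title: Optional[str] = None,
    n_grid: Optional[Mapping[tuple[str, str], int]] = None,
) -> SummaryTable:
    """Assemble the formatted summary table for one dataset.

    *results* must hold a ResponseResults per response, with a letter
    display iff options.phc.  The caption's n statement uses *n_grid*
    (per-treatment record counts) when given, else the per-response cell
    counts of the first response.
    """
    missing = [r for r in dataset.response_names if r not in results]
    if missing:
        raise RuntimeError(f"results missing for responses {missing!r}")
    for resp, rr in results.items():
        if options.phc and rr.letters is None:
            raise RuntimeError(f"letters missing for response {resp!r}")
        if not options.phc and rr.letters is not None:
            raise RuntimeError("letters supplied although phc is off")
        if options.format == "pooled_sem" and rr.pooled is None:
            raise RuntimeError(f"pooled SEM missing for response {resp!r}")

    pooled = options.format == "pooled_sem"
    treatments = dataset.treatments
    rows: list[TableRow] = []
    letters_used: set[str] = set()
    for resp in dataset.response_names:
        rr = results[resp]
        by_treatment = {c.treatment: c for c in rr.cells}
        cells = []
        for t in treatments:
            c = by_treatment[t]
            if pooled:
                text = _fmt(c.mean, options.sig_digits)
            else:
                text = (f"{_fmt(c.mean, options.sig_digits)} ± "
                        f"{_fmt(c.sem, options.sig_digits)}")
            sup = ""
            if options.phc and rr.letters is not None:
                sup = rr.letters.assignment.get(t, "")
            letters_used.update(sup)
            cells.append(CellDisplay(text, sup))
        anova = rr.anova
        p_a = anova.p_for_factor(dataset.factor_a_name)
        p_b = anova.p_for_factor(dataset.factor_b_name)
        p_ab = anova.term("A×B").p
        ps = tuple(
            format_pvalue(p, options.p_decimals) if p is not None else "—"
            for p in (p_a, p_b, p_ab)
        )
        rows.append(TableRow(
            response=resp,
            cells=tuple(cells),
            pooled=_fmt(rr.pooled, options.sig_digits) if pooled else None,
            p_values=ps,
        ))

    if n_grid is None:
        first = results[dataset.response_names[0]]
        n_grid = {c.treatment: c.n for c in first.cells}
    caption = build_caption(
        options, n_grid, letters_used,
        (dataset.factor_a_name, dataset.factor_b_name),
    )
    return SummaryTable(
        title=title if title is not None else dataset.source_sheet,
        factor_a=dataset.factor_a_name,
        factor_b=dataset.factor_b_name,
        levels_a=tuple(dataset.levels_a),
        levels_b=tuple(dataset.levels_b),
        pooled=pooled,
        p_headers=(
            dataset.factor_a_name,
            dataset.factor_b_name,
            _interaction_abbrev(dataset.factor_a_name, dataset.factor_b_name),
        ),
        rows=tuple(rows),
        caption=caption,
    )


def build_caption(
    options: TableOptions,
    n_info: Mapping[tuple[str, str], int],
    letters_used: set[str],
    factor_names: tuple[str, str],
) -> str:
    """Auto-generated caption: summary type, n statement, letter sentence
    (only when letters were used) and the interaction abbreviation."""
    ns = sorted({n for n in n_info.values() if n > 0})
    if len(ns) == 1:
        n_text = f"n = {ns[0]} per treatment group"
    else:
        n_text = f"n = {ns[0]}-{ns[-1]} per treatment group"
    lead = ("Values are means and pooled SEM"
            if options.format == "pooled_sem"
            else "Values are means ± SEM")
    parts = [f"{lead}, {n_text}."]
    if letters_used:
        lo, hi = min(letters_used), max(letters_used)
        span = lo if lo == hi else f"{lo}-{hi}"
        alpha = trim_trailing_zeros(f"{options.alpha:.10f}")
        parts.append(
            f"{span}Means in a row without a common superscript letter "
            f"differ (P < {alpha}) as analyzed by two-way ANOVA and the "
            f"{options.test.upper()} test."
        )
    fa, fb = factor_names
    parts.append(
        f"{_interaction_abbrev(fa, fb)} = {fa} × {fb} interaction effect."
    )
    return " ".join(parts)
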