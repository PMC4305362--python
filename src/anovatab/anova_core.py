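"""Two-way ANOVA with interaction and the cell-means collapse.

The two-way fit uses sequential (Type I) sums of squares obtained from
nested least-squares projections: SS(A), SS(B|A), SS(AxB|A,B) and the
residual.  In balanced designs the decomposition is orthogonal and
order-invariant; in unbalanced designs the factor order matters, which is
why fit_two_way takes an explicit factor_order.

All post-hoc work uses the cell-means model: the two factors collapsed into
one factor with a*b levels (one per treatment), whose pooled within-cell
variance equals the two-way fit's residual mean square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data_io import Dataset
from .exceptions import DesignError, NumericError, ReplicationError

__all__ = [
    "CellSummary",
    "AnovaTerm",
    "AnovaResult",
    "CellMeansFit",
    "DesignReport",
    "cell_summaries",
    "fit_two_way",
    "fit_cell_means",
    "cell_means_from_summary",
    "check_design",
]


@dataclass(frozen=True)
class CellSummary:
    """Mean, SEM and count of the non-missing values in one treatment cell."""

    level_a: str
    level_b: str
    mean: float
    sem: float
    n: int

    @property
    def treatment(self) -> tuple[str, str]:
        return (self.level_a, self.level_b)

    @property
    def sd(self) -> float:
        """Sample standard deviation implied by the SEM."""
        return self.sem * np.sqrt(self.n)


@dataclass(frozen=True)
class AnovaTerm:
    name: str            # "A", "B", "A×B" or "residual"
    ss: float
    df: int
    ms: float
    f: Optional[float]   # absent for the residual term
    p: Optional[float]


@dataclass(frozen=True)
class AnovaResult:
    """Sequential two-way decomposition in the order given by factor_order."""

    terms: tuple[AnovaTerm, ...]
    mse: float
    residual_df: int
    factor_order: tuple[str, str]

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def p_for_factor(self, factor_name: str) -> Optional[float]:
        """p-value of the main effect of a factor identified by name."""
        if factor_name == self.factor_order[0]:
            return self.term("A").p
        if factor_name == self.factor_order[1]:
            return self.term("B").p
        raise KeyError(factor_name)


@dataclass(frozen=True)
class CellMeansFit:
    """One-way collapse of the a*b treatments, sharing the two-way MSE."""

    cells: tuple[CellSummary, ...]
    mse: float
    df_error: int
    balanced: bool

    @property
    def treatments(self) -> list[tuple[str, str]]:
        return [c.treatment for c in self.cells]

    @property
    def means(self) -> dict[tuple[str, str], float]:
        return {c.treatment: c.mean for c in self.cells}

    @property
    def ns(self) -> dict[tuple[str, str], int]:
        return {c.treatment: c.n for c in self.cells}


@dataclass(frozen=True)
class DesignReport:
    balanced: bool
    n_grid: dict[tuple[str, str], int]
    min_n: int
    max_n: int
    warnings: tuple[str, ...]


# --------------------------------------------------------------------------

def _cell_values(
    dataset: Dataset, response: str
) -> dict[tuple[str, str], np.ndarray]:
    """Non-missing values per treatment cell, cells in (A x B) order."""
    if response not in dataset.response_names:
        raise KeyError(f"no response {response!r} in dataset")
    cells: dict[tuple[str, str], list[float]] = {
        t: [] for t in dataset.treatments
    }
    for la, lb, resp in dataset.records:
        v = resp[response]
        if v is not None:
            cells[(la, lb)].append(float(v))
    for t, vals in cells.items():
        if not vals:
            raise DesignError(
                f"incomplete factorial: no observations of {response!r} "
                f"for treatment {t[0]}-{t[1]}"
            )
    return {t: np.asarray(v, dtype=float) for t, v in cells.items()}


def cell_summaries(dataset: Dataset, response: str) -> list[CellSummary]:
    """Per-treatment mean, SEM and n, cells in (A-order x B-order) sequence."""
    out = []
    for (la, lb), vals in _cell_values(dataset, response).items():
        n = len(vals)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        out.append(CellSummary(la, lb, float(np.mean(vals)), sem, n))
    return out


def _dummies(labels: Sequence[str], order: Sequence[str]) -> np.ndarray:
    """Treatment-coded dummy columns for every level after the first."""
    cols = [
        (np.asarray(labels) == lev).astype(float) for lev in order[1:]
    ]
    return np.column_stack(cols) if cols else np.empty((len(labels), 0))


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r)


def fit_two_way(
    dataset: Dataset,
    response: str,
    factor_order: Optional[tuple[str, str]] = None,
) -> AnovaResult:
    """Sequential two-way ANOVA with interaction for one response.

    factor_order defaults to (factor_a_name, factor_b_name); the reversed
    order gives the other Type-I table for unbalanced data.
    """
    cells = _cell_values(dataset, response)
    ns = np.array([len(v) for v in cells.values()])
    if np.all(ns == 1):
        raise ReplicationError(
            "two-way ANOVA will not be conducted and a table will not be "
            "generated: there is only one observation for each treatment"
        )
    if factor_order is None:
        factor_order = (dataset.factor_a_name, dataset.factor_b_name)
    if set(factor_order) != {dataset.factor_a_name, dataset.factor_b_name}:
        raise KeyError(f"factor_order {factor_order!r} does not name the "
                       "dataset's two factors")

    la_all, lb_all, y = [], [], []
    for la, lb, resp in dataset.records:
        v = resp[response]
        if v is not None:
            la_all.append(la)
            lb_all.append(lb)
            y.append(float(v))
    yv = np.asarray(y)
    n_total = len(yv)
    first_is_a = factor_order[0] == dataset.factor_a_name
    lab1 = la_all if first_is_a else lb_all
    lab2 = lb_all if first_is_a else la_all
    order1 = dataset.levels_a if first_is_a else dataset.levels_b
    order2 = dataset.levels_b if first_is_a else dataset.levels_a
    a, b = len(order1), len(order2)
    df_resid = n_total - a * b
    if df_resid < 1:
        raise NumericError(
            f"zero residual degrees of freedom ({n_total} observations, "
            f"{a * b} treatments)"
        )

    d1 = _dummies(lab1, order1)
    d2 = _dummies(lab2, order2)
    inter = np.column_stack(
        [d1[:, i] * d2[:, j] for i in range(d1.shape[1])
         for j in range(d2.shape[1])]
    ) if d1.shape[1] and d2.shape[1] else np.empty((n_total, 0))
    ones = np.ones((n_total, 1))
    x_a = np.hstack([ones, d1])
    x_b = np.hstack([x_a, d2])
    x_ab = np.hstack([x_b, inter])

    rss0 = float(np.sum((yv - yv.mean()) ** 2))
    rss_a = _rss(yv, x_a)
    rss_b = _rss(yv, x_b)
    rss_ab = _rss(yv, x_ab)
    ss = [max(rss0 - rss_a, 0.0), max(rss_a - rss_b, 0.0),
          max(rss_b - rss_ab, 0.0), max(rss_ab, 0.0)]
    dfs = [a - 1, b - 1, (a - 1) * (b - 1), df_resid]
    mse = ss[3] / df_resid

    terms = []
    for name, s, d in zip(("A", "B", "A×B"), ss, dfs):
        ms = s / d if d else 0.0
        if mse > 0:
            f = ms / mse
            p = float(stats.f.sf(f, d, df_resid))
        else:
            f = p = None
        terms.append(AnovaTerm(name, s, d, ms, f, p))
    terms.append(AnovaTerm("residual", ss[3], df_resid, mse, None, None))
    return AnovaResult(tuple(terms), mse, df_resid, tuple(factor_order))


def fit_cell_means(dataset: Dataset, response: str) -> CellMeansFit:
    """Collapse the two factors into a*b treatments and pool the within-cell
    variance into the MSE (identical to the two-way residual mean square)."""
    cells = _cell_values(dataset, response)
    ns = np.array([len(v) for v in cells.values()])
    if np.all(ns == 1):
        raise ReplicationError(
            "two-way ANOVA will not be conducted and a table will not be "
            "generated: there is only one observation for each treatment"
        )
    n_total = int(ns.sum())
    df_error = n_total - len(cells)
    if df_error < 1:
        raise NumericError("zero error degrees of freedom")
    within = sum(
        float(np.sum((v - v.mean()) ** 2)) for v in cells.values()
    )
    mse = within / df_error
    summaries = cell_summaries(dataset, response)
    return CellMeansFit(
        cells=tuple(summaries),
        mse=mse,
        df_error=df_error,
        balanced=bool(np.all(ns == ns[0])),
    )


def cell_means_from_summary(
    cells: Sequence[CellSummary], df_error: Optional[int] = None
) -> CellMeansFit:
    """Rebuild a cell-means fit from published per-cell means, SEMs and n.

    The MSE is the pooled within-cell variance implied by the SEMs:
    sum((n_i - 1) * n_i * SEM_i^2) / sum(n_i - 1).  With a common n this is
    n * mean(SEM^2).  Useful for re-analysing tables that print only
    summary statistics.
    """
    ns = np.array([c.n for c in cells])
    if np.any(ns < 2):
        raise DesignError("summary reconstruction needs n >= 2 per cell")
    num = sum((c.n - 1) * c.n * c.sem**2 for c in cells)
    den = int(np.sum(ns - 1))
    if df_error is None:
        df_error = den
    return CellMeansFit(
        cells=tuple(cells),
        mse=float(num / den),
        df_error=int(df_error),
        balanced=bool(np.all(ns == ns[0])),
    )


def check_design(dataset: Dataset) -> DesignReport:
    """Report balancedness, the per-cell n grid and missing-value warnings."""
    grid = {t: 0 for t in dataset.treatments}
    for la, lb, _resp in dataset.records:
        grid[(la, lb)] += 1
    warnings = []
    empty = [t for t, n in grid.items() if n == 0]
    if empty:
        warnings.append(f"empty treatment cells: {empty!r}")
    for resp in dataset.response_names:
        miss = sum(1 for _, _, r in dataset.records if r[resp] is None)
        if miss:
            warnings.append(
                f"response {resp!r} has {miss} missing value(s); per-cell n "
                "differs from the record count and SEMs use the reduced n"
            )
    counts = [n for n in grid.values() if n > 0]
    return DesignReport(
        balanced=len(set(counts)) == 1 and not empty,
        n_grid=grid,
        min_n=min(counts),
        max_n=max(counts),
        warnings=tuple(warnings),
    )
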