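"""All-pairwise comparisons of treatment means under the cell-means model.

Five procedures over the a*b treatment means, all sharing the pooled MSE:

- LSD: per-pair t tests, optionally Bonferroni- or Holm-adjusted;
- Tukey-Kramer: studentized-range p-values (Tukey HSD when balanced);
- SNK and Duncan: step-down protected range tests that return decisions,
  not per-pair p-values (a contained sub-range of a non-significant range
  is never declared significant);
- Westfall-style: free step-down max-|t| resampling under the complete
  null, deterministic given a seed.

Unequal cell sizes use the Kramer per-pair standard error
sqrt(MSE/2 * (1/n_i + 1/n_j)) throughout the range statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .anova_core import CellMeansFit
from .exceptions import InputError, NumericError

__all__ = [
    "MCPConfig",
    "PairwiseResult",
    "lsd_pairwise",
    "adjust_pvalues",
    "tukey_kramer",
    "range_test",
    "westfall_adjust",
    "pairwise",
    "significance_matrix",
]

TESTS = ("tukey", "snk", "duncan", "lsd", "westfall")
ADJUSTMENTS = ("none", "bonferroni", "holm")


@dataclass(frozen=True)
class MCPConfig:
    """Choice of all-pairwise procedure and its knobs.

    adjust applies only to the LSD test (endpoint of the range-test family);
    nsim and seed only to the resampling-based Westfall procedure.
    """

    test: str = "tukey"
    alpha: float = 0.05
    adjust: str = "none"
    nsim: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise InputError(f"unknown test {self.test!r}; one of {TESTS}")
        if self.adjust not in ADJUSTMENTS:
            raise InputError(
                f"unknown adjustment {self.adjust!r}; one of {ADJUSTMENTS}"
            )
        if self.adjust != "none" and self.test != "lsd":
            raise InputError("p-value adjustment applies to the LSD test only")
        if not 0.0 < self.alpha < 1.0:
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.nsim < 1000:
            raise InputError("nsim must be at least 1000")


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[tuple[str, str], tuple[str, str]]
    estimate: float          # mean difference, first minus second
    se: float                # standard error matching `statistic`
    statistic: float         # t for LSD/Westfall, q for range tests
    p_raw: Optional[float]   # absent for SNK/Duncan (decision-only tests)
    p_adj: Optional[float]
    significant: bool


def _check_fit(fit: CellMeansFit) -> None:
    if fit.df_error < 1:
        raise NumericError("fit has no error degrees of freedom")
    if fit.mse <= 0:
        raise NumericError(
            "MSE is zero: no within-cell variability, pairwise tests are "
            "degenerate"
        )


def _pairs(fit: CellMeansFit):
    return list(itertools.combinations(fit.cells, 2))


# --------------------------------------------------------------------------
# LSD and p-value adjustment

def lsd_pairwise(fit: CellMeansFit, config: MCPConfig) -> list[PairwiseResult]:
    """Fisher's LSD: all pairwise t tests with the pooled MSE.

    Unadjusted by default; with adjust="bonferroni" or "holm" this is the
    Bonferroni / Holm test of the standard design textbooks.
    """
    _check_fit(fit)
    raws, rows = [], []
    for c1, c2 in _pairs(fit):
        se = float(np.sqrt(fit.mse * (1 / c1.n + 1 / c2.n)))
        est = c1.mean - c2.mean
        t = est / se
        p = float(2 * stats.t.sf(abs(t), fit.df_error))
        raws.append(p)
        rows.append((c1, c2, est, se, t, p))
    adj = adjust_pvalues(raws, config.adjust)
    return [
        PairwiseResult(
            pair=(c1.treatment, c2.treatment),
            estimate=est, se=se, statistic=t,
            p_raw=p, p_adj=pa, significant=pa < config.alpha,
        )
        for (c1, c2, est, se, t, p), pa in zip(rows, adj)
    ]


def adjust_pvalues(p: Sequence[float], method: str = "none") -> list[float]:
    """Adjust a family of p-values for multiplicity.

    bonferroni: min(1, m*p_i).  holm: step-down — sort ascending and take
    the running maximum of min(1, (m-rank+1)*p), restored to input order.
    """
    p = [float(v) for v in p]
    if any(not 0.0 <= v <= 1.0 for v in p):
        raise InputError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "none":
        return list(p)
    if method == "bonferroni":
        return [min(1.0, m * v) for v in p]
    if method == "holm":
        order = sorted(range(m), key=lambda i: p[i])
        out = [0.0] * m
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, min(1.0, (m - rank) * p[i]))
            out[i] = running
        return out
    raise InputError(f"unknown adjustment {method!r}")


# --------------------------------------------------------------------------
# studentized-range procedures

@lru_cache(maxsize=None)
def _q_critical(gamma: float, span: int, df: int) -> float:
    """Upper gamma-quantile of the studentized range with `span` means."""
    return float(stats.studentized_range.ppf(1.0 - gamma, span, df))


def tukey_kramer(fit: CellMeansFit, config: MCPConfig) -> list[PairwiseResult]:
    """Tukey-Kramer: single-step studentized-range test with k = a*b groups.

    In balanced designs this is Tukey's HSD; unequal n uses the Kramer
    per-pair standard error.
    """
    _check_fit(fit)
    k = len(fit.cells)
    pairs = _pairs(fit)
    qs, rows = [], []
    for c1, c2 in pairs:
        se = float(np.sqrt(fit.mse / 2 * (1 / c1.n + 1 / c2.n)))
        est = c1.mean - c2.mean
        qs.append(abs(est) / se)
        rows.append((c1, c2, est, se))
    ps = np.atleast_1d(stats.studentized_range.sf(np.asarray(qs), k,
                                                  fit.df_error))
    ps = np.clip(ps, 0.0, 1.0)
    return [
        PairwiseResult(
            pair=(c1.treatment, c2.treatment),
            estimate=est, se=se, statistic=q,
            p_raw=float(p), p_adj=float(p), significant=float(p) < config.alpha,
        )
        for (c1, c2, est, se), q, p in zip(rows, qs, ps)
    ]


def _duncan_gamma(span: int, alpha: float) -> float:
    """Duncan's per-span level 1 - (1-alpha)^(span-1)."""
    return 1.0 - (1.0 - alpha) ** (span - 1)


def range_test(fit: CellMeansFit, config: MCPConfig) -> list[PairwiseResult]:
    """SNK or Duncan multiple range test with step-down protection.

    Means are ordered descending; a pair spanning p ordered positions is
    tested against q(gamma_p, p, df) with gamma_p = alpha (SNK) or
    1-(1-alpha)^(p-1) (Duncan).  A range contained in a non-significant
    range is declared non-significant without testing, so these tests
    produce decisions only (p_raw and p_adj are absent).
    """
    if config.test not in ("snk", "duncan"):
        raise InputError("range_test handles the snk and duncan tests only")
    _check_fit(fit)
    cells = sorted(fit.cells, key=lambda c: (-c.mean, c.treatment))
    k = len(cells)
    sig: dict[tuple[int, int], bool] = {}
    nonsig_ranges: list[tuple[int, int]] = []
    for span in range(k, 1, -1):
        gamma = (config.alpha if config.test == "snk"
                 else _duncan_gamma(span, config.alpha))
        crit = _q_critical(gamma, span, fit.df_error)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(i0 <= i and j <= j0 for i0, j0 in nonsig_ranges):
                sig[(i, j)] = False
                nonsig_ranges.append((i, j))
                continue
            c1, c2 = cells[i], cells[j]
            se = float(np.sqrt(fit.mse / 2 * (1 / c1.n + 1 / c2.n)))
            q = abs(c1.mean - c2.mean) / se
            if q > crit:
                sig[(i, j)] = True
            else:
                sig[(i, j)] = False
                nonsig_ranges.append((i, j))
    index = {c.treatment: i for i, c in enumerate(cells)}
    out = []
    for c1, c2 in _pairs(fit):
        i, j = sorted((index[c1.treatment], index[c2.treatment]))
        se = float(np.sqrt(fit.mse / 2 * (1 / c1.n + 1 / c2.n)))
        est = c1.mean - c2.mean
        out.append(PairwiseResult(
            pair=(c1.treatment, c2.treatment),
            estimate=est, se=se, statistic=abs(est) / se,
            p_raw=None, p_adj=None, significant=sig[(i, j)],
        ))
    return out


# --------------------------------------------------------------------------
# resampling max-t

def westfall_adjust(
    fit: CellMeansFit, config: MCPConfig
) -> list[PairwiseResult]:
    """Free step-down max-|t| resampling adjustment of the pairwise t tests.

    Treatment means are simulated under the complete null as independent
    normals with variance MSE/n_i together with a chi-square-scaled variance
    estimate on df_error degrees of freedom, so each simulated pairwise
    statistic is marginally t-distributed.  Adjusted p-values follow the
    step-down max-statistic rule with monotonicity enforcement, and are
    clipped from below by the raw p-values.  Deterministic given the seed.
    """
    _check_fit(fit)
    pairs = _pairs(fit)
    m = len(pairs)
    ns = np.array([c.n for c in fit.cells], dtype=float)
    idx = {c.treatment: i for i, c in enumerate(fit.cells)}
    rows, tobs, praw = [], [], []
    for c1, c2 in pairs:
        se = float(np.sqrt(fit.mse * (1 / c1.n + 1 / c2.n)))
        est = c1.mean - c2.mean
        t = est / se
        rows.append((c1, c2, est, se, t))
        tobs.append(abs(t))
        praw.append(float(2 * stats.t.sf(abs(t), fit.df_error)))
    tobs = np.asarray(tobs)

    rng = np.random.default_rng(config.seed)
    z = rng.standard_normal((config.nsim, len(ns))) / np.sqrt(ns)
    s2 = rng.chisquare(fit.df_error, config.nsim) / fit.df_error
    tsim = np.empty((config.nsim, m))
    for p_i, (c1, c2, *_rest) in enumerate(rows):
        i, j = idx[c1.treatment], idx[c2.treatment]
        denom = np.sqrt(s2 * (1 / c1.n + 1 / c2.n))
        tsim[:, p_i] = np.abs(z[:, i] - z[:, j]) / denom

    order = np.argsort(-tobs)           # most extreme hypothesis first
    # successive maxima over the not-yet-rejected set
    run_max = np.maximum.accumulate(tsim[:, order[::-1]], axis=1)[:, ::-1]
    padj_sorted = (run_max >= tobs[order]).mean(axis=0)
    padj_sorted = np.maximum.accumulate(padj_sorted)   # monotone step-down
    padj = np.empty(m)
    padj[order] = padj_sorted
    padj = np.maximum(padj, praw)

    return [
        PairwiseResult(
            pair=(c1.treatment, c2.treatment),
            estimate=est, se=se, statistic=t,
            p_raw=pr, p_adj=float(pa), significant=float(pa) < config.alpha,
        )
        for (c1, c2, est, se, t), pr, pa in zip(rows, praw, padj)
    ]


# --------------------------------------------------------------------------

def pairwise(fit: CellMeansFit, config: MCPConfig) -> list[PairwiseResult]:
    """Dispatch to the procedure named by config.test."""
    if config.test == "lsd":
        return lsd_pairwise(fit, config)
    if config.test == "tukey":
        return tukey_kramer(fit, config)
    if config.test in ("snk", "duncan"):
        return range_test(fit, config)
    if config.test == "westfall":
        return westfall_adjust(fit, config)
    raise InputError(f"unknown test {config.test!r}")


def significance_matrix(
    results: Sequence[PairwiseResult],
) -> dict[frozenset, bool]:
    """Symmetric pair -> significance map consumed by the letter display."""
    return {frozenset(r.pair): r.significant for r in results}
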