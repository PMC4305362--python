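"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import anovatab as at
from anovatab.anova_core import CellMeansFit, CellSummary

# ---------------------------------------------------------------------------
# printed expectations for the worked-example table (means ± SEM, n = 9):
# p-values of diet, weight and their interaction, and Tukey superscripts in
# treatment order (HF-Lean, HF-Overweight, LF-Lean, LF-Overweight).

PRINTED_P = {
    "Asp": ("0.824", "0.824", "0.604"), "Glu": ("0.757", "0.984", "0.951"),
    "Asn": ("0.477", "0.922", "0.068"), "Ser": ("0.576", "<0.001", "0.807"),
    "Gln": ("0.801", "<0.001", "0.676"), "His": ("0.236", "0.906", "0.028"),
    "Gly": ("0.254", "<0.001", "0.955"), "Thr": ("0.365", "0.223", "0.481"),
    "Cit": ("0.057", "<0.001", "<0.001"), "Arg": ("0.001", "<0.001", "0.642"),
    "beta.Ala": ("0.064", "<0.001", "0.123"),
    "Taurine": ("<0.001", "<0.001", "0.006"),
    "Ala": ("<0.001", "0.252", "<0.001"), "Tyr": ("0.865", "0.069", "0.268"),
    "Trp": ("0.658", "0.703", "0.42"), "Met": ("0.77", "0.521", "0.991"),
    "Val": ("0.017", "<0.001", "0.048"), "Phe": ("0.988", "0.645", "0.211"),
    "Ile": ("0.035", "<0.001", "0.674"), "Leu": ("0.83", "<0.001", "0.465"),
    "Orn": ("0.786", "<0.001", "0.381"), "Pro": ("0.96", "<0.001", "0.196"),
    "Cys": ("0.279", "<0.001", "0.648"), "Lys": ("0.957", "<0.001", "0.273"),
}

PRINTED_LETTERS = {
    "Ser": ("a", "b", "a", "b"), "Gln": ("b", "a", "b", "a"),
    "Gly": ("a", "b", "a", "b"), "Cit": ("a", "c", "b", "ab"),
    "Arg": ("b", "c", "a", "c"), "beta.Ala": ("b", "a", "b", "a"),
    "Taurine": ("a", "c", "a", "b"), "Ala": ("b", "c", "b", "a"),
    "Val": ("c", "a", "c", "b"), "Ile": ("b", "a", "b", "a"),
    "Leu": ("b", "a", "b", "a"), "Orn": ("b", "a", "b", "a"),
    "Pro": ("b", "a", "b", "a"), "Cys": ("b", "a", "b", "a"),
    "Lys": ("c", "a", "bc", "ab"),
}

TREATMENTS = (("HF", "Lean"), ("HF", "Overweight"),
              ("LF", "Lean"), ("LF", "Overweight"))

POOLED_SEM_PRINTED = {"Asp": "4.2", "Ser": "9.87", "Gln": "21.6",
                      "Ala": "14.7", "Met": "6.66"}


@pytest.fixture(scope="session")
def plasma() -> at.Dataset:
    return at.plasma_dataset()


@pytest.fixture
def toy_dataset() -> at.Dataset:
    """2x2 design, n = 2: cells {(1,3), (2,4), (5,7), (6,8)}."""
    rows = [("a1", "b1", 1.0), ("a1", "b1", 3.0),
            ("a1", "b2", 2.0), ("a1", "b2", 4.0),
            ("a2", "b1", 5.0), ("a2", "b1", 7.0),
            ("a2", "b2", 6.0), ("a2", "b2", 8.0)]
    return at.Dataset("A", "B", [(a, b, {"y": v}) for a, b, v in rows],
                      source_sheet="toy")


@pytest.fixture
def toy_fit_2() -> CellMeansFit:
    """Two treatments, means 2 and 6, n = 2 each, MSE = 2, df = 4."""
    cells = (CellSummary("a1", "b1", 2.0, 1.0, 2),
             CellSummary("a2", "b1", 6.0, 1.0, 2))
    return CellMeansFit(cells, mse=2.0, df_error=4, balanced=True)


def fit_from_table(response: str, df_error: int = 32) -> CellMeansFit:
    """Cell-means fit rebuilt from the printed means/SEMs of one response."""
    cells = tuple(
        CellSummary(t[0], t[1], m, s, at.synthetic.PLASMA_N)
        for t, (m, s) in at.PLASMA_SUMMARY[response].items()
    )
    return at.cell_means_from_summary(cells, df_error=df_error)


def random_balanced_fit(rng: np.random.Generator, k: int = 4,
                        n: int = 9, spread: float = 1.0) -> CellMeansFit:
    """Random k-treatment balanced fit with a chi-square-distributed MSE."""
    assert k == 4, "labels below assume a 2x2 collapse"
    df = k * (n - 1)
    mse = rng.chisquare(df) / df
    cells = tuple(
        CellSummary(la, lb, float(rng.normal(0.0, spread)),
                    float(np.sqrt(mse / n)), n)
        for la, lb in TREATMENTS
    )
    return CellMeansFit(cells, mse=mse, df_error=df, balanced=True)


def significant_pairs(results) -> frozenset:
    return frozenset(frozenset(r.pair) for r in results if r.significant)


# ---------------------------------------------------------------------------
# brute-force letter-display oracle.  Each letter is a clique of the
# non-significance graph; a sound and complete display must cover every
# non-significant *pair* (edge) with a shared letter and give every
# treatment at least one letter.  The minimum letter count is therefore the
# minimum number of cliques covering all edges and all vertices, found here
# by exhaustive enumeration over maximal cliques (any clique in a cover can
# be enlarged to a maximal one without losing coverage).

def min_letter_count(treatments, sig: dict) -> int:
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(treatments)
    for fs, flag in sig.items():
        if not flag:
            graph.add_edge(*tuple(fs))
    cliques = [frozenset(c) for c in nx.find_cliques(graph)]
    edges = [frozenset(e) for e in graph.edges]
    for size in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, size):
            if all(any(e <= c for c in combo) for e in edges) and \
                    all(any(t in c for c in combo) for t in treatments):
                return size
    return len(cliques)


def random_sig_instance(rng: np.random.Generator, k: int):
    """Random symmetric significance matrix plus distinct means."""
    treatments = [(f"T{i}", "x") for i in range(k)]
    means = {t: float(rng.normal(0, 1)) for t in treatments}
    sig = {
        frozenset(p): bool(rng.random() < 0.45)
        for p in itertools.combinations(treatments, 2)
    }
    return treatments, sig, means
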