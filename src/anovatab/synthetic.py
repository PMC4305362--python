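"""Synthetic two-factor data with known ground truth.

Two generators are provided.  generate_dataset draws independent normal
observations per treatment cell with configurable means, a common standard
deviation and per-cell sample sizes — exactly the sampling model the
two-way ANOVA assumes.  dataset_from_summary reconstructs raw-looking data
from published per-cell means and SEMs by scaling a fixed standardized
vector, so the reconstructed cells reproduce the printed means and SEMs
(and hence the pooled MSE) exactly.

PLASMA_SUMMARY ships the package's worked example: per-cell means and SEMs
(n = 9) of 24 plasma amino-acid concentrations (nmol/ml) from a rat study
crossing diet (high-fat vs low-fat) with weight class (lean vs overweight).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .data_io import Dataset
from .exceptions import InputError

__all__ = [
    "GeneratorSpec",
    "generate_dataset",
    "dataset_from_summary",
    "write_fixture_workbook",
    "PLASMA_SUMMARY",
    "plasma_dataset",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Sampling plan for one normally distributed response.

    Defaults mirror the package's worked example: a 2x2 diet-by-weight
    design with n = 9 per cell, cell means from the serine response and a
    common SD of 20.9 (the pooled within-cell SD implied by that row's
    SEMs).
    """

    levels_a: tuple[str, ...] = ("HF", "LF")
    levels_b: tuple[str, ...] = ("Lean", "Overweight")
    cell_means: tuple[tuple[float, ...], ...] = ((359.0, 294.0),
                                                 (353.0, 292.0))
    sigma: float = 20.9
    n: Union[int, tuple[tuple[int, ...], ...]] = 9
    missing_rate: float = 0.0
    seed: int = 0
    response: str = "y"
    factor_a: str = "Diet"
    factor_b: str = "Weight"

    def n_grid(self) -> np.ndarray:
        a, b = len(self.levels_a), len(self.levels_b)
        grid = np.broadcast_to(np.asarray(self.n, dtype=int), (a, b))
        return np.array(grid)

    def validate(self) -> None:
        a, b = len(self.levels_a), len(self.levels_b)
        if a < 2 or b < 2:
            raise InputError("each factor needs at least two levels")
        means = np.asarray(self.cell_means, dtype=float)
        if means.shape != (a, b):
            raise InputError(
                f"cell_means shape {means.shape} does not match ({a}, {b})"
            )
        if not self.sigma > 0:
            raise InputError("sigma must be positive")
        if np.any(self.n_grid() < 1):
            raise InputError("per-cell n must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise InputError("missing_rate must be in [0, 1)")


def generate_dataset(spec: GeneratorSpec) -> Dataset:
    """Draw a dataset from the spec; deterministic given spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.cell_means, dtype=float)
    ns = spec.n_grid()
    records = []
    for i, la in enumerate(spec.levels_a):
        for j, lb in enumerate(spec.levels_b):
            values = rng.normal(means[i, j], spec.sigma, size=ns[i, j])
            for v in values:
                keep = (spec.missing_rate == 0.0
                        or rng.random() >= spec.missing_rate)
                records.append(
                    (la, lb, {spec.response: float(v) if keep else None})
                )
    return Dataset(spec.factor_a, spec.factor_b, records,
                   source_sheet="synthetic")


# --------------------------------------------------------------------------
# exact-moment reconstruction from published summaries

def _exact_cell(mean: float, sem: float, n: int) -> np.ndarray:
    """n values whose sample mean and SEM equal the given ones exactly."""
    if n < 2:
        raise InputError("need n >= 2 to realize a SEM")
    base = np.arange(1.0, n + 1.0)
    z = (base - base.mean()) / base.std(ddof=1)
    return mean + sem * np.sqrt(n) * z


def dataset_from_summary(
    summary: Mapping[str, Mapping[tuple[str, str], tuple[float, float]]],
    n: int,
    factor_a: str,
    factor_b: str,
    sheet: str = "reconstructed",
) -> Dataset:
    """Build a dataset whose cells reproduce printed means and SEMs exactly.

    summary maps response -> {(level_a, level_b): (mean, sem)}; every
    response must cover the same treatments.  The reconstruction preserves
    every statistic that depends only on cell means, SEMs and n — the
    two-way F tests, the pooled MSE and all pairwise procedures — which is
    what makes published summary tables re-analysable.
    """
    responses = list(summary)
    if not responses:
        raise InputError("empty summary")
    treatments = list(summary[responses[0]])
    cells: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for resp in responses:
        if list(summary[resp]) != treatments:
            raise InputError("responses cover different treatments")
        cells[resp] = {
            t: _exact_cell(m, s, n) for t, (m, s) in summary[resp].items()
        }
    records = []
    for t in treatments:
        for i in range(n):
            records.append(
                (t[0], t[1],
                 {resp: float(cells[resp][t][i]) for resp in responses})
            )
    return Dataset(factor_a, factor_b, records, source_sheet=sheet)


def write_fixture_workbook(
    datasets: Sequence[Dataset], path: Union[str, Path]
) -> None:
    """Write one sheet per dataset, readable back by read_workbook."""
    if not datasets:
        raise InputError("no datasets to write")
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for ds in datasets:
            ds.to_frame().to_excel(
                writer, sheet_name=ds.source_sheet, index=False
            )


# --------------------------------------------------------------------------
# worked example: rat plasma amino acids, diet x weight class, n = 9

_T = (("HF", "Lean"), ("HF", "Overweight"), ("LF", "Lean"),
      ("LF", "Overweight"))

_PLASMA_ROWS: dict[str, tuple[tuple[float, float], ...]] = {
    "Asp": ((45.3, 2.39), (47.6, 2.97), (46.2, 2.96), (45.3, 3.45)),
    "Glu": ((88.4, 3.23), (88.6, 1.16), (87.8, 2.58), (87.6, 3.18)),
    "Asn": ((128, 5.71), (114, 10.4), (120, 5.62), (133, 6.58)),
    "Ser": ((359, 10.3), (294, 4.39), (353, 7.43), (292, 3.76)),
    "Gln": ((562, 18.3), (645, 11.1), (559, 9.43), (655, 19.6)),
    "His": ((124, 3.18), (115, 2.95), (120, 4.08), (130, 5.89)),
    "Gly": ((392, 6.91), (305, 7.3), (384, 7.32), (297, 5.68)),
    "Thr": ((379, 7.42), (359, 11.6), (381, 8.62), (376, 12.6)),
    "Cit": ((79.9, 2.66), (53.8, 1.63), (69.6, 3.37), (73.9, 1.84)),
    "Arg": ((251, 8.09), (197, 6.4), (279, 7.46), (219, 4.46)),
    "beta.Ala": ((13.6, 0.884), (31.4, 1.52), (13.1, 0.611), (26.8, 1.91)),
    "Taurine": ((648, 17.2), (469, 13.1), (670, 11.9), (572, 12)),
    "Ala": ((471, 10.2), (403, 13.6), (492, 7.54), (585, 9.22)),
    "Tyr": ((131, 4.25), (135, 4.04), (125, 5.7), (139, 5.32)),
    "Trp": ((110, 3.28), (114, 4.78), (115, 2.61), (113, 3.4)),
    "Met": ((108, 5.39), (112, 3.65), (107, 4.83), (110, 4.8)),
    "Val": ((253, 9.61), (331, 6.74), (249, 10.1), (289, 9.63)),
    "Phe": ((111, 3.7), (108, 3.84), (106, 3.81), (113, 3.44)),
    "Ile": ((152, 4.19), (206, 4.01), (144, 4.77), (195, 3.68)),
    "Leu": ((212, 4.56), (308, 7.56), (216, 6.34), (302, 5.79)),
    "Orn": ((68.8, 1.58), (81.4, 1.51), (67.8, 2.06), (83.3, 1.25)),
    "Pro": ((277, 7.04), (342, 8.59), (286, 5.32), (334, 4.52)),
    "Cys": ((165, 4.53), (197, 7), (157, 3.2), (194, 6.58)),
    "Lys": ((252, 8.82), (291, 5.17), (259, 8.32), (282, 5.42)),
}

#: response -> {(diet level, weight level): (mean, SEM)}, n = 9 per cell
PLASMA_SUMMARY: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    resp: {t: (float(m), float(s)) for t, (m, s) in zip(_T, rows)}
    for resp, rows in _PLASMA_ROWS.items()
}

PLASMA_N = 9


def plasma_dataset(
    responses: Optional[Sequence[str]] = None, sheet: str = "Plasma"
) -> Dataset:
    """The worked-example dataset, reconstructed from its summary table."""
    if responses is None:
        responses = list(PLASMA_SUMMARY)
    summary = {r: PLASMA_SUMMARY[r] for r in responses}
    return dataset_from_summary(summary, PLASMA_N, "Diet", "Weight",
                                sheet=sheet)
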