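"""Interaction plots: cell means of one factor traced across the other.

One PDF page per response; the x-axis carries the levels of factor B and
one line per level of factor A connects the cell means, so parallel traces
indicate the absence of interaction.  Optional ±SEM whiskers.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.backends.backend_pdf import PdfPages  # noqa: E402
from matplotlib.figure import Figure  # noqa: E402

from .anova_core import cell_summaries  # noqa: E402
from .data_io import Dataset  # noqa: E402
from .exceptions import InputError  # noqa: E402

__all__ = ["interaction_plot", "render_interaction_plots"]


def interaction_plot(
    dataset: Dataset, response: str, error_bars: bool = False
) -> Figure:
    """Figure with one line per level of factor A over the levels of B."""
    cells = {c.treatment: c for c in cell_summaries(dataset, response)}
    levels_a, levels_b = dataset.levels_a, dataset.levels_b
    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    xs = range(len(levels_b))
    for la in levels_a:
        means = [cells[(la, lb)].mean for lb in levels_b]
        sems = [cells[(la, lb)].sem for lb in levels_b]
        if error_bars:
            ax.errorbar(xs, means, yerr=sems, marker="o", capsize=3,
                        label=la)
        else:
            ax.plot(xs, means, marker="o", label=la)
    ax.set_xticks(list(xs))
    ax.set_xticklabels(levels_b)
    ax.set_xlabel(dataset.factor_b_name)
    ax.set_ylabel(response)
    ax.set_title(response)
    ax.legend(title=dataset.factor_a_name)
    fig.tight_layout()
    return fig


def render_interaction_plots(
    dataset: Dataset,
    responses: Optional[Sequence[str]],
    path: Union[str, Path],
    error_bars: bool = False,
) -> None:
    """Write a multi-page PDF, one interaction plot per response."""
    if responses is None:
        responses = dataset.response_names
    if not responses:
        raise InputError("no responses to plot")
    with PdfPages(path) as pdf:
        for resp in responses:
            fig = interaction_plot(dataset, resp, error_bars=error_bars)
            pdf.savefig(fig)
            plt.close(fig)
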