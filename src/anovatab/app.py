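"""Command-line orchestration: workbook in, RTF tables (and PDF plots) out.

For every selected sheet and every response the pipeline runs cell
summaries, the two-way fit (both factor orders when requested and the
design is unbalanced), the cell-means fit, the chosen pairwise procedure,
the letter display and — for the pooled layout — the pooled SEM, then
renders everything into a single RTF document.  Sheets that fail
validation are reported without aborting the rest; a sheet with exactly
one observation per treatment triggers the replication alert and produces
no table.

Exit codes: 0 all sheets ok, 1 some sheets failed, 2 no sheet succeeded.
"""

from __future__ import annotations

import argparse
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import anova_core, data_io, mcp, rtf_writer, summarize
from .exceptions import AnovatabError, ReplicationError
from .letters import compact_letter_display
from .plots import render_interaction_plots
from .summarize import ResponseResults, SummaryTable, TableOptions

log = logging.getLogger("anovatab")

__all__ = ["RunConfig", "SheetStatus", "RunReport", "analyze_dataset",
           "run", "main"]


@dataclass(frozen=True)
class RunConfig:
    input: Path
    sheets: Union[str, tuple[str, ...]] = "all"   # "all" or sheet names
    options: TableOptions = field(default_factory=TableOptions)
    mcp_config: mcp.MCPConfig = field(default_factory=mcp.MCPConfig)
    both_orders: bool = False
    rtf_out: Optional[Path] = None
    pdf_out: Optional[Path] = None
    log_level: str = "INFO"


@dataclass(frozen=True)
class SheetStatus:
    sheet: str
    ok: bool
    message: str = ""
    n_responses: int = 0


@dataclass(frozen=True)
class RunReport:
    statuses: tuple[SheetStatus, ...]
    tables: tuple[SummaryTable, ...]
    rtf_path: Optional[Path]
    pdf_path: Optional[Path]
    warnings: tuple[str, ...]

    @property
    def exit_code(self) -> int:
        oks = [s.ok for s in self.statuses]
        if all(oks):
            return 0
        return 1 if any(oks) else 2


def analyze_dataset(
    dataset: data_io.Dataset,
    options: TableOptions,
    mcp_config: mcp.MCPConfig,
    both_orders: bool = False,
) -> tuple[list[SummaryTable], list[str]]:
    """Full per-sheet analysis; returns its table(s) and warnings.

    With both_orders and an unbalanced design, a second table with the
    factors entered in reverse order is produced (the sequential p-values
    differ between orders in unbalanced data)."""
    report = anova_core.check_design(dataset)
    warnings = list(report.warnings)
    log.info("sheet %r: balanced=%s, n grid %s", dataset.source_sheet,
             report.balanced, report.n_grid)
    fa, fb = dataset.factor_a_name, dataset.factor_b_name
    orders: list[tuple[str, str]] = [(fa, fb)]
    if both_orders and not report.balanced:
        orders.append((fb, fa))
    tables = []
    for order in orders:
        results: dict[str, ResponseResults] = {}
        for resp in dataset.response_names:
            cells = anova_core.cell_summaries(dataset, resp)
            anova = anova_core.fit_two_way(dataset, resp, order)
            fit = anova_core.fit_cell_means(dataset, resp)
            letters = None
            if options.phc:
                pw = mcp.pairwise(fit, mcp_config)
                letters = compact_letter_display(
                    mcp.significance_matrix(pw), fit.means
                )
            pooled = (summarize.pooled_sem(fit)
                      if options.format == "pooled_sem" else None)
            results[resp] = ResponseResults(cells, anova, letters, pooled)
        title = dataset.source_sheet
        if len(orders) > 1 and order != orders[0]:
            title += f" (factor order: {order[0]}, {order[1]})"
        tables.append(summarize.build_table(
            dataset, results, options, title=title, n_grid=report.n_grid
        ))
    return tables, warnings


def _sheet_names(config: RunConfig) -> list[str]:
    path = Path(config.input)
    if path.suffix.lower() == ".csv":
        return [path.stem]
    book = pd.ExcelFile(path, engine="openpyxl")
    names = list(book.sheet_names)
    if config.sheets != "all":
        wanted = list(config.sheets)
        missing = [s for s in wanted if s not in names]
        if missing:
            raise data_io.SheetNotFoundError(
                f"sheets not in workbook: {missing!r}"
            )
        names = wanted
    return names


def run(config: RunConfig) -> RunReport:
    """Run the pipeline over every selected sheet of the input file."""
    path = Path(config.input)
    if not path.exists():
        raise data_io.InputError(f"no such file: {path}")
    statuses: list[SheetStatus] = []
    tables: list[SummaryTable] = []
    warnings: list[str] = []
    first_dataset: Optional[data_io.Dataset] = None
    for name in _sheet_names(config):
        try:
            if path.suffix.lower() == ".csv":
                dataset = data_io.read_dataset(path)
            else:
                dataset = data_io.read_dataset(path, sheet=name)
            sheet_tables, sheet_warnings = analyze_dataset(
                dataset, config.options, config.mcp_config,
                config.both_orders,
            )
        except ReplicationError as exc:
            statuses.append(SheetStatus(name, False, str(exc)))
            log.warning("sheet %r: %s", name, exc)
            continue
        except (AnovatabError, KeyError) as exc:
            statuses.append(SheetStatus(name, False, str(exc)))
            log.warning("sheet %r failed: %s", name, exc)
            continue
        tables.extend(sheet_tables)
        warnings.extend(f"{name}: {w}" for w in sheet_warnings)
        statuses.append(SheetStatus(name, True,
                                    n_responses=len(dataset.response_names)))
        if first_dataset is None:
            first_dataset = dataset

    rtf_path = pdf_path = None
    if tables and config.rtf_out is not None:
        doc = rtf_writer.render_rtf(tables)
        rtf_writer.write_document(doc, config.rtf_out)
        rtf_path = Path(config.rtf_out)
        log.info("wrote %d table(s) to %s", doc.tables, rtf_path)
    if first_dataset is not None and config.pdf_out is not None:
        render_interaction_plots(first_dataset, None, config.pdf_out)
        pdf_path = Path(config.pdf_out)
        log.info("wrote interaction plots to %s", pdf_path)
    return RunReport(tuple(statuses), tuple(tables), rtf_path, pdf_path,
                     tuple(warnings))


# --------------------------------------------------------------------------
# CLI

def _build_parser() -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(
        prog="anovatab",
        description="Publication-ready two-way ANOVA tables with post-hoc "
                    "letter displays, exported to RTF.",
    )
    p.add_argument("input", type=Path, help=".xlsx or .csv input file")
    p.add_argument("--config", type=Path, default=None,
                   help="YAML file with the same keys as the flags")
    p.add_argument("--alpha", type=float, default=0.05)
    p.add_argument("--sig-digits", type=int, default=3)
    p.add_argument("--p-decimals", type=int, default=3)
    p.add_argument("--test", choices=mcp.TESTS, default="tukey")
    p.add_argument("--adjust", choices=mcp.ADJUSTMENTS, default="none",
                   help="p-value adjustment (LSD test only)")
    p.add_argument("--format", choices=("per-group", "pooled"),
                   default="per-group")
    p.add_argument("--no-phc", action="store_true",
                   help="table without post-hoc superscripts")
    p.add_argument("--both-orders", action="store_true",
                   help="emit a second table with reversed factor order "
                        "for unbalanced designs")
    p.add_argument("--sheets", default="all",
                   help="comma-separated sheet names (default: all)")
    p.add_argument("--out", type=Path, default=None, help="RTF output path")
    p.add_argument("--plots", type=Path, default=None,
                   help="PDF output path for interaction plots "
                        "(first selected sheet)")
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--nsim", type=int, default=10_000)
    p.add_argument("--log-level", default="INFO")
    return p


def config_from_args(args: argparse.Namespace) -> RunConfig:
    options = TableOptions(
        alpha=args.alpha,
        sig_digits=args.sig_digits,
        p_decimals=args.p_decimals,
        format="pooled_sem" if args.format == "pooled" else "per_group_sem",
        phc=not args.no_phc,
        test=args.test,
    )
    mcp_config = mcp.MCPConfig(
        test=args.test, alpha=args.alpha, adjust=args.adjust,
        nsim=args.nsim, seed=args.seed,
    )
    sheets: Union[str, tuple[str, ...]] = "all"
    if args.sheets != "all":
        sheets = tuple(s.strip() for s in args.sheets.split(",") if s.strip())
    out = args.out
    if out is None:
        out = args.input.with_suffix(".rtf")
    return RunConfig(
        input=args.input, sheets=sheets, options=options,
        mcp_config=mcp_config, both_orders=args.both_orders,
        rtf_out=out, pdf_out=args.plots, log_level=args.log_level,
    )


def main(argv: Optional[Sequence[str]] = None) -> int:
    parser = _build_parser()
    args = parser.parse_args(argv)
    if args.config is not None:
        defaults = yaml.safe_load(Path(args.config).read_text()) or {}
        parser.set_defaults(**{k.replace("-", "_"): v
                               for k, v in defaults.items()})
        args = parser.parse_args(argv)
    logging.basicConfig(level=args.log_level.upper(),
                        format="%(levelname)s %(name)s: %(message)s")
    try:
        report = run(config_from_args(args))
    except AnovatabError as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 2
    for status in report.statuses:
        mark = "ok" if status.ok else "FAILED"
        detail = (f"{status.n_responses} response(s)" if status.ok
                  else status.message)
        print(f"sheet {status.sheet!r}: {mark} ({detail})")
    for w in report.warnings:
        print(f"warning: {w}")
    if report.rtf_path:
        print(f"tables written to {report.rtf_path}")
    if report.pdf_path:
        print(f"interaction plots written to {report.pdf_path}")
    return report.exit_code


def cli() -> None:  # console-script entry point
    sys.exit(main())
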