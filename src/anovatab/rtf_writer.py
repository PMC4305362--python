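"""Serialization of summary tables to a minimal, portable RTF dialect.

The writer emits plain RTF 1.x row/cell control words with a two-row
nested header (factor A levels spanning their factor B sub-columns via
horizontal cell merges), superscript letters via {\\super ...}, and a
caption paragraph after each table.  Output is 7-bit ASCII; characters
outside ASCII (±, ×) are written as \\uN? escapes.  Rendering is
deterministic: identical input gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from .exceptions import InputError
from .summarize import SummaryTable

__all__ = ["RtfDocument", "render_rtf", "write_document"]

_PREAMBLE = (
    "{\\rtf1\\ansi\\ansicpg1252\\deff0"
    "{\\fonttbl{\\f0\\froman Times New Roman;}}\\fs20\n"
)


@dataclass(frozen=True)
class RtfDocument:
    content: str
    tables: int


def _escape(text: str) -> str:
    out = []
    for ch in text:
        if ch in "\\{}":
            out.append("\\" + ch)
        elif ord(ch) < 128:
            out.append(ch)
        else:
            cp = ord(ch)
            if cp > 32767:
                cp -= 65536
            out.append(f"\\u{cp}?")
    return "".join(out)


def _cell_text(cell_text: str, superscript: str = "", bold: bool = False) -> str:
    body = _escape(cell_text)
    if superscript:
        body += "{\\super " + _escape(superscript) + "}"
    if bold:
        body = "{\\b " + body + "}"
    return body


def _row(defs: Sequence[tuple[int, str]], contents: Sequence[str]) -> str:
    """One table row: defs = (right edge in twips, merge control) per cell."""
    parts = ["\\trowd\\trgaph108"]
    for edge, merge in defs:
        parts.append(f"{merge}\\cellx{edge}")
    parts.append("\\pard\\intbl\\qc ")
    for content in contents:
        parts.append(content + "\\cell ")
    parts.append("\\row\n")
    return "".join(parts)


def _column_widths(table: SummaryTable) -> list[int]:
    """Fixed widths proportional to header text length (twips)."""
    labels = ["Variable"]
    labels += [lb for _la in table.levels_a for lb in table.levels_b]
    if table.pooled:
        labels.append("Pooled SEM")
    labels += list(table.p_headers)
    return [max(900, 380 + 150 * len(lab)) for lab in labels]


def _render_table(table: SummaryTable) -> str:
    widths = _column_widths(table)
    edges = []
    x = 0
    for w in widths:
        x += w
        edges.append(x)
    nb = len(table.levels_b)
    pooled_col = 1 + len(table.levels_a) * nb if table.pooled else None

    # header row 1: Variable | A levels spanning b columns | (Pooled) | P-value
    defs1, cont1 = [], []
    defs1.append((edges[0], "\\clvmgf"))
    cont1.append(_cell_text("Variable", bold=True))
    col = 1
    for la in table.levels_a:
        for j in range(nb):
            defs1.append((edges[col], "\\clmgf" if j == 0 else "\\clmrg"))
            cont1.append(_cell_text(la, bold=True) if j == 0 else "")
            col += 1
    if pooled_col is not None:
        defs1.append((edges[col], "\\clvmgf"))
        cont1.append(_cell_text("Pooled SEM", bold=True))
        col += 1
    for j in range(3):
        defs1.append((edges[col], "\\clmgf" if j == 0 else "\\clmrg"))
        cont1.append(_cell_text("P-value", bold=True) if j == 0 else "")
        col += 1

    # header row 2: blanks under the vertical merges, B levels, p columns
    defs2, cont2 = [], []
    defs2.append((edges[0], "\\clvmrg"))
    cont2.append("")
    col = 1
    for _la in table.levels_a:
        for lb in table.levels_b:
            defs2.append((edges[col], ""))
            cont2.append(_cell_text(lb, bold=True))
            col += 1
    if pooled_col is not None:
        defs2.append((edges[col], "\\clvmrg"))
        cont2.append("")
        col += 1
    for head in table.p_headers:
        defs2.append((edges[col], ""))
        cont2.append(_cell_text(head, bold=True))
        col += 1

    out = ["{\\pard\\sb120\\sa60\\b " + _escape(table.title) + "\\par}\n"]
    out.append(_row(defs1, cont1))
    out.append(_row(defs2, cont2))
    plain = [(e, "") for e in edges]
    for row in table.rows:
        contents = [_cell_text(row.response)]
        contents += [_cell_text(c.text, c.superscript) for c in row.cells]
        if table.pooled:
            contents.append(_cell_text(row.pooled or ""))
        contents += [_cell_text(p) for p in row.p_values]
        out.append(_row(plain, contents))
    out.append("{\\pard\\sb60\\sa240 " + _escape(table.caption) + "\\par}\n")
    return "".join(out)


def render_rtf(tables: Sequence[SummaryTable]) -> RtfDocument:
    """Render one RTF document containing one table per SummaryTable."""
    if not tables:
        raise InputError("no tables to render")
    content = _PREAMBLE + "".join(_render_table(t) for t in tables) + "}\n"
    return RtfDocument(content=content, tables=len(tables))


def write_document(doc: RtfDocument, path: Union[str, Path]) -> None:
    """Write the document as ASCII bytes; idempotent and byte-exact."""
    Path(path).write_text(doc.content, encoding="ascii")
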