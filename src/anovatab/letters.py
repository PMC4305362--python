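"""Compact letter display by insert-and-absorb.

Treatments that are *not* significantly different share at least one letter;
treatments without a common letter differ at the chosen level.  By
convention, when no pair is significant no letters are shown at all.

The algorithm starts from a single column holding every treatment.  Each
significant pair found together in a column splits that column into two
copies, one without each member; columns contained in another column are
absorbed.  Columns become letters a, b, c, ... ordered by the descending
maximum mean of their members, so "a" always attaches to the largest mean.
The result is sound and complete with respect to the input matrix but not
guaranteed to use the theoretical minimum number of letters.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_lowercase
from typing import Mapping

from .exceptions import InputError

__all__ = ["LetterDisplay", "compact_letter_display"]

Treatment = tuple[str, str]


@dataclass(frozen=True)
class LetterDisplay:
    """Treatment -> letter-string map; empty strings when nothing differs."""

    assignment: dict[Treatment, str]
    any_significant: bool

    @property
    def letters_used(self) -> set[str]:
        return set("".join(self.assignment.values()))


def _normalize(sig: Mapping, treatments: list[Treatment]) -> dict[frozenset, bool]:
    norm: dict[frozenset, bool] = {}
    for key, flag in sig.items():
        fs = frozenset(key)
        if len(fs) != 2:
            raise InputError(f"pair key {key!r} does not name two treatments")
        if fs in norm and norm[fs] != bool(flag):
            raise InputError(
                f"inconsistent significance flags for pair {sorted(fs)!r}"
            )
        norm[fs] = bool(flag)
    for i, t1 in enumerate(treatments):
        for t2 in treatments[i + 1:]:
            if frozenset((t1, t2)) not in norm:
                raise InputError(f"pair ({t1!r}, {t2!r}) missing from matrix")
    return norm


def _absorb(columns: list[frozenset]) -> list[frozenset]:
    """Drop columns contained in another column; keep first of duplicates."""
    kept: list[frozenset] = []
    for col in columns:
        if any(col <= other for other in kept):
            continue
        kept = [c for c in kept if not c < col]
        kept.append(col)
    return kept


def compact_letter_display(
    sig: Mapping, means: Mapping[Treatment, float]
) -> LetterDisplay:
    """Build the letter display for a pairwise significance pattern.

    *sig* maps each unordered treatment pair (2-tuple or frozenset key) to
    True when the pair is significantly different; *means* anchors letter
    order ("a" = highest mean, ties broken by treatment label).
    """
    treatments = sorted(means, key=lambda t: (-means[t], t))
    norm = _normalize(sig, treatments)
    if not any(norm.values()):
        return LetterDisplay({t: "" for t in treatments}, False)

    sig_pairs = [fs for fs, flag in norm.items() if flag]
    # deterministic processing order: by (larger mean, smaller mean) labels
    def _pair_key(fs: frozenset):
        hi, lo = sorted(fs, key=lambda t: (-means[t], t))
        return (-means[hi], hi, -means[lo], lo)

    columns: list[frozenset] = [frozenset(treatments)]
    for fs in sorted(sig_pairs, key=_pair_key):
        u, v = sorted(fs, key=lambda t: (-means[t], t))
        new_cols: list[frozenset] = []
        for col in columns:
            if u in col and v in col:
                new_cols.append(col - {v})
                new_cols.append(col - {u})
            else:
                new_cols.append(col)
        columns = _absorb(new_cols)

    def _col_key(col: frozenset):
        best = min(col, key=lambda t: (-means[t], t))
        return (-means[best], best)

    columns = sorted(columns, key=_col_key)
    if len(columns) > len(ascii_lowercase):
        raise InputError("more than 26 letter groups; display not possible")
    assignment = {
        t: "".join(
            ascii_lowercase[i] for i, col in enumerate(columns) if t in col
        )
        for t in treatments
    }
    return LetterDisplay(assignment, True)
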