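"""Majority-rule consensus and pairwise identity.

A family consensus is the per-column most frequent base over a set of
aligned copies; columns dominated by gaps are dropped. Pairwise identity of
terminal regions (e.g. the conserved 5′ 100 bp of avian families) is
computed from a global alignment; the denominator convention is explicit
because published percentage identities rarely state one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional

import edlib

from .align import global_align

_ALPHABET = set("ACGTN-")
_BASE_ORDER = "ACGT"  # tie-break order


@dataclass
class AlignedCopySet:
    """Equal-length gapped rows over the A/C/G/T/N/- alphabet."""

    family_id: str
    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("rows must have equal length")
        bad = set("".join(self.rows).upper()) - _ALPHABET
        if bad:
            raise ValueError(f"invalid alignment characters: {sorted(bad)}")
        self.rows = [r.upper() for r in self.rows]


def majority_consensus(aln: AlignedCopySet, gap_rule_fraction: float = 0.5,
                       tie_report: Optional[list[int]] = None) -> str:
    """Per-column majority base.

    Columns whose gap frequency reaches ``gap_rule_fraction`` are omitted.
    N never wins a majority (all-N columns emit N). Ties between bases are
    broken in the fixed order A<C<G<T; tied column indices (0-based, in
    alignment coordinates) are appended to ``tie_report`` when given.
    """
    n = len(aln.rows)
    out: list[str] = []
    for j in range(len(aln.rows[0])):
        col = [r[j] for r in aln.rows]
        counts = Counter(col)
        if counts.get("-", 0) / n >= gap_rule_fraction:
            continue
        base_counts = {b: counts.get(b, 0) for b in _BASE_ORDER}
        top = max(base_counts.values())
        if top == 0:
            out.append("N")
            continue
        winners = [b for b in _BASE_ORDER if base_counts[b] == top]
        if len(winners) > 1 and tie_report is not None:
            tie_report.append(j)
        out.append(winners[0])
    return "".join(out)


def pairwise_identity(a: str, b: str, region_len: Optional[int] = None,
                      denominator: str = "aligned_columns") -> float:
    """Identity of two sequences from a global alignment.

    ``region_len`` truncates both sequences to their first ``region_len``
    bases (terminal-region comparisons). ``denominator`` is either
    ``aligned_columns`` (matches over alignment columns, dual-gap columns
    cannot occur) or ``shorter_seq`` (matches over the shorter input).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if denominator not in ("aligned_columns", "shorter_seq"):
        raise ValueError("denominator must be aligned_columns or shorter_seq")
    a, b = a.upper(), b.upper()
    if region_len is not None:
        a, b = a[:region_len], b[:region_len]
    aln = global_align(a, b)
    denom = aln.aligned_cols if denominator == "aligned_columns" else min(len(a), len(b))
    return aln.matches / denom


def star_align(reference: str, seqs: dict[str, str]) -> dict[str, str]:
    """Project every sequence onto reference coordinates via an edit-distance
    alignment (works for nucleotide or protein strings).

    Insertions relative to the reference are dropped (rows live in reference
    coordinates); deletions become gaps. Not a general-purpose multiple
    aligner — a utility for synthetic fixtures and simulator output.
    """
    out: dict[str, str] = {}
    for name, s in seqs.items():
        s = s.upper()
        res = edlib.align(s, reference.upper(), task="path", mode="NW")
        row = []
        qi = 0
        for n_ops, op in _cigar_ops(res["cigar"]):
            if op in "=XM":
                row.append(s[qi:qi + n_ops])
                qi += n_ops
            elif op == "I":   # present in s, absent in reference: drop
                qi += n_ops
            elif op == "D":   # absent in s
                row.append("-" * n_ops)
        out[name] = "".join(row)
    return out


def align_to_reference(reference: str, seqs: dict[str, str],
                       family_id: str = "family") -> AlignedCopySet:
    """Star-align nucleotide copies against a reference consensus."""
    rows = star_align(reference, seqs)
    return AlignedCopySet(family_id=family_id, row_ids=list(rows),
                          rows=list(rows.values()))


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""
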