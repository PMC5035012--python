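"""Zinc-finger detection and R2 clade assignment.

R2 clades are distinguished by the number and type of zinc fingers proximal
to (upstream of) the reverse-transcriptase domain:

    R2A: 3 fingers (2 CCHH + 1 CCHC)    R2C: 2 fingers (2 CCHH)
    R2B: 2 fingers (1 CCHH + 1 CCHC)    R2D: 1 finger  (1 CCHH)

A finger is matched as C-x(2,4)-C-x(8,20)-H-x(3,5)-[H|C]; the fourth
coordinating residue decides CCHH vs CCHC. Matching is greedy
leftmost-first with minimal spacings, resuming after each match, so the
reported finger multiset is deterministic. Anything outside the four exact
count patterns is reported as ``unknown`` — never an exception.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .io import read_fasta

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX*")

# lazy quantifiers -> leftmost match with lexicographically minimal
# (second C, H, last residue) positions
_FINGER_RE = re.compile(r"C.{2,4}?C.{8,20}?H.{3,5}?[HC]")

CLADE_BY_COUNTS = {(2, 1): "R2A", (1, 1): "R2B", (2, 0): "R2C", (1, 0): "R2D"}


@dataclass(frozen=True)
class ZincFinger:
    kind: str   # "CCHH" | "CCHC"
    start: int  # 0-based position of the first coordinating C
    end: int    # position after the last coordinating residue


@dataclass
class CladeCall:
    clade: str
    n_cchh: int
    n_cchc: int
    evidence: list[ZincFinger] = field(default_factory=list)


def detect_zinc_fingers(protein: str, region_end: Optional[int] = None) -> list[ZincFinger]:
    """Scan the pre-RT region of a protein for CCHH/CCHC fingers.

    ``region_end`` marks the start of the RT domain; only fingers ending at or
    before it are reported. When absent, the N-terminal 40% of the protein is
    scanned (fingers sit proximal to, i.e. upstream of, the RT domain).
    """
    if not protein:
        raise ValueError("empty protein sequence")
    protein = protein.upper()
    for i, aa in enumerate(protein):
        if aa not in VALID_AA:
            raise ValueError(f"invalid amino-acid character {aa!r} at position {i + 1}")
    if region_end is None:
        region_end = max(1, int(0.4 * len(protein)))
    region = protein[:region_end]
    fingers: list[ZincFinger] = []
    pos = 0
    while True:
        m = _FINGER_RE.search(region, pos)
        if m is None:
            break
        kind = "CCHH" if m.group()[-1] == "H" else "CCHC"
        fingers.append(ZincFinger(kind=kind, start=m.start(), end=m.end()))
        pos = m.end()
    return fingers


def classify_clade(fingers: Iterable[ZincFinger]) -> CladeCall:
    """Map a finger multiset to a clade; order-insensitive, total counts only."""
    fingers = list(fingers)
    counts = Counter(f.kind for f in fingers)
    n_cchh, n_cchc = counts.get("CCHH", 0), counts.get("CCHC", 0)
    clade = CLADE_BY_COUNTS.get((n_cchh, n_cchc), "unknown")
    return CladeCall(clade=clade, n_cchh=n_cchh, n_cchc=n_cchc, evidence=fingers)


def classify_protein(protein: str, region_end: Optional[int] = None) -> CladeCall:
    return classify_clade(detect_zinc_fingers(protein, region_end))


def scan_fasta(path: str | Path, region_end: Optional[int] = None) -> pd.DataFrame:
    """Batch mode: protein FASTA in, one clade-call row per record.

    Finger coordinates are reported 1-based inclusive as "start-end" spans.
    """
    rows = []
    for name, seq in read_fasta(path).items():
        call = classify_protein(seq, region_end)
        rows.append(dict(
            id=name, clade=call.clade, n_cchh=call.n_cchh, n_cchc=call.n_cchc,
            fingers=",".join(f"{f.kind}:{f.start + 1}-{f.end}" for f in call.evidence),
        ))
    return pd.DataFrame(rows, columns=["id", "clade", "n_cchh", "n_cchc", "fingers"])
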