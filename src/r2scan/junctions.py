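"""Copy discovery, junction-offset calling and target-specificity analysis.

This is the analytical core: locate element copies in a genome (k-mer
seed-and-extend against the family consensus), align the sequence flanking
each copy end back onto the target 28S gene, and express each junction as an
offset from the canonical insertion site. A 5′ offset of 110 means the
insertion replaced 110 bp of 28S upstream of the site — the "apparent
movement" geometry. Families are then classified as target-specific,
partially specific or non-specific from the per-copy calls, and a family's
3′ UTR is screened for a degraded 28S-derived segment (recognisable because
its identity to the gene is lower than that of the true downstream flanks).

Junction tolerances are asymmetric by default (tol5=2, tol3=0): bottom-strand
cleavage at the target site is strictly determined while top-strand cleavage
varies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import edlib

from .align import Alignment, local_align
from .io import revcomp
from .syngenome import ElementFamily, TargetReference


@dataclass
class ElementCopy:
    copy_id: str
    contig: str
    start: int
    end: int
    strand: str
    family_id: str
    identity_to_consensus: float
    cons_start: int = 0
    cons_end: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty copy interval")
        if not 0.0 <= self.identity_to_consensus <= 1.0:
            raise ValueError("identity outside [0,1]")


@dataclass
class FlankHit:
    """One flank aligned back onto the target gene.

    ``projected`` is the target coordinate of the element boundary: for a 5′
    flank, the position right after the last target base preceding the
    element; for a 3′ flank, the position of the first target base following
    it. ``identity`` is matches over the examined flank window, so random
    (non-target) flanks score low even when a short local hit exists.
    """

    projected: int
    identity: float
    aligned_cols: int
    unaligned_gap: int


@dataclass
class JunctionCall:
    copy_id: str
    flank5_hit: Optional[FlankHit]
    flank3_hit: Optional[FlankHit]
    offset5: Optional[int]
    offset3: Optional[int]
    specificity: str  # canonical | shifted_5prime | shifted_3prime | non_adjacent
    flags: list[str] = field(default_factory=list)


@dataclass
class FamilySpecificity:
    family_id: str
    n_copies: int
    n_adjacent: int
    n_non_adjacent: int
    verdict: str  # target_specific | partially_specific | non_specific
    modal_offset5: Optional[int]


@dataclass
class UTRTargetMatch:
    family_id: str
    utr_interval: Optional[tuple[int, int]]
    target_interval: Optional[tuple[int, int]]
    identity: Optional[float]
    flank_identity: float
    is_utr_internal: bool


def _edlib_identity(a: str, b: str) -> float:
    """Identity of two long sequences from an edit-distance alignment."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, task="distance")
    aln_len = max(len(a), len(b))
    return max(0.0, 1.0 - res["editDistance"] / aln_len)


def _extend(genome: str, cons: str, gpos: int, cpos: int, direction: int,
            match: int = 1, mismatch: int = -2, xdrop: int = 15) -> tuple[int, int]:
    """Ungapped X-drop extension; returns (genome, consensus) positions one
    past the last base of the best-scoring extension."""
    best = score = 0
    best_g, best_c = gpos, cpos
    g, c = gpos, cpos
    while True:
        g2, c2 = g + direction, c + direction
        if direction > 0:
            if g2 > len(genome) or c2 > len(cons):
                break
            pair = (genome[g2 - 1], cons[c2 - 1])
        else:
            if g2 < 0 or c2 < 0:
                break
            pair = (genome[g2], cons[c2])
        score += match if pair[0] == pair[1] else mismatch
        g, c = g2, c2
        if score > best:
            best, best_g, best_c = score, g, c
        elif best - score > xdrop:
            break
    return best_g, best_c


def find_copies(
    genome: dict[str, str] | str,
    family_consensus: str,
    family_id: str = "family",
    k: int = 12,
    min_len: int = 100,
    min_identity: float = 0.7,
) -> list[ElementCopy]:
    """Locate copies of one family by k-mer seeding and ungapped extension.

    Seeds on both strands are chained by diagonal, chains are extended
    outwards with an X-drop rule, merged, scored for identity against the
    matching consensus interval (edit-distance alignment), and resolved to a
    non-overlapping best-hit set.
    """
    if not 8 <= k <= 32:
        raise ValueError("k must be in [8, 32]")
    if min_identity < 0.6:
        raise ValueError("min_identity must be >= 0.6")
    if not family_consensus:
        raise ValueError("empty family consensus")
    contigs = {"genome": genome} if isinstance(genome, str) else genome
    if not contigs or any(not s for s in contigs.values()):
        raise ValueError("empty genome")
    cons = family_consensus.upper()
    index: dict[str, list[int]] = {}
    for i in range(len(cons) - k + 1):
        index.setdefault(cons[i:i + k], []).append(i)

    raw: list[tuple[str, str, int, int, int, int, float]] = []
    for contig, seq in contigs.items():
        seq = seq.upper()
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            hits = []
            for g in range(len(s) - k + 1):
                for c in index.get(s[g:g + k], ()):
                    hits.append((g, c))
            # chain by diagonal and proximity
            hits.sort()
            chains: list[list[tuple[int, int]]] = []
            for g, c in hits:
                placed = False
                for ch in reversed(chains):
                    lg, lc = ch[-1]
                    if abs((g - c) - (lg - lc)) <= 40 and 0 <= g - lg <= 500 and c >= lc:
                        ch.append((g, c))
                        placed = True
                        break
                if not placed:
                    chains.append([(g, c)])
            for ch in chains:
                if len(ch) < 2 and len(cons) > 3 * k:
                    continue
                g0, c0 = ch[0]
                g1, c1 = ch[-1]
                gs, cs = _extend(s, cons, g0, c0, -1)
                ge, ce = _extend(s, cons, g1 + k, c1 + k, +1)
                if ge - gs < min_len:
                    continue
                ident = _edlib_identity(s[gs:ge], cons[cs:ce])
                if ident < min_identity:
                    continue
                if strand == "+":
                    start, end = gs, ge
                else:
                    start, end = len(s) - ge, len(s) - gs
                raw.append((contig, strand, start, end, cs, ce, ident))

    # best-hit resolution: keep longest/highest-identity non-overlapping
    raw.sort(key=lambda r: (-(r[3] - r[2]) * r[6], r[0], r[2]))
    kept: list[tuple[str, str, int, int, int, int, float]] = []
    for cand in raw:
        overlap = False
        for other in kept:
            if cand[0] != other[0]:
                continue
            ov = min(cand[3], other[3]) - max(cand[2], other[2])
            if ov > 0.5 * min(cand[3] - cand[2], other[3] - other[2]):
                overlap = True
                break
        if not overlap:
            kept.append(cand)
    kept.sort(key=lambda r: (r[0], r[2]))
    return [
        ElementCopy(
            copy_id=f"{family_id}_copy{i:03d}", contig=contig, start=start,
            end=end, strand=strand, family_id=family_id,
            identity_to_consensus=round(ident, 4), cons_start=cs, cons_end=ce,
        )
        for i, (contig, strand, start, end, cs, ce, ident) in enumerate(kept)
    ]


def _flank_hit(flank: str, target: TargetReference, side: str,
               window: int) -> Optional[FlankHit]:
    """Project one flank onto the target; identity is over the flank window."""
    if not flank:
        return None
    aln: Alignment = local_align(flank, target.sequence)
    if aln.aligned_cols == 0:
        return FlankHit(projected=0, identity=0.0, aligned_cols=0, unaligned_gap=0)
    identity = aln.matches / len(flank)
    # Project to the last/first *aligned* target base. Unaligned flank bases
    # between the alignment and the element boundary (target-site alteration
    # or copy-boundary slop) are recorded and flagged, not projected through.
    if side == "5":
        tail = len(flank) - aln.q_end  # flank bases between alignment and element
        projected = aln.t_end
    else:
        tail = aln.q_start
        projected = aln.t_start
    return FlankHit(projected=projected, identity=identity,
                    aligned_cols=aln.aligned_cols, unaligned_gap=tail)


def call_junctions(
    copy: ElementCopy,
    genome: dict[str, str] | str,
    target: TargetReference,
    window: int = 60,
    min_flank_identity: float = 0.8,
    tol5: int = 2,
    tol3: int = 0,
) -> JunctionCall:
    """Call both junction offsets of one copy against the canonical site.

    The ``window`` bases on each side of the copy are locally aligned to the
    target gene; a flank counts as adjacent when its window identity reaches
    ``min_flank_identity``. Offsets follow the target coordinate system
    regardless of element strand (minus-strand copies have their flanks
    swapped and reverse-complemented before projection). Unaligned junction
    gaps ≤ 3 bp are absorbed into the offset and flagged (target-site
    alteration upon insertion); larger gaps are flagged separately.
    """
    if window < 30:
        raise ValueError("window must be >= 30")
    seq = genome if isinstance(genome, str) else genome[copy.contig]
    flags: list[str] = []
    left = seq[max(0, copy.start - window):copy.start]
    right = seq[copy.end:copy.end + window]
    if len(left) < window or len(right) < window:
        flags.append("contig_edge")
    if copy.strand == "+":
        flank5, flank3 = left, right
    else:
        flank5, flank3 = revcomp(right), revcomp(left)

    hit5 = _flank_hit(flank5, target, "5", window)
    hit3 = _flank_hit(flank3, target, "3", window)
    cs = target.canonical_site

    def qualifies(h: Optional[FlankHit]) -> bool:
        return h is not None and h.identity >= min_flank_identity

    offset5 = cs - hit5.projected if qualifies(hit5) else None
    offset3 = hit3.projected - cs if qualifies(hit3) else None
    for side, h in (("5", hit5), ("3", hit3)):
        if qualifies(h) and h.unaligned_gap:
            flags.append(f"junction_gap_{side}:{h.unaligned_gap}"
                         + ("" if h.unaligned_gap <= 3 else ":large"))

    if offset5 is None and offset3 is None:
        spec = "non_adjacent"
    else:
        ok5 = offset5 is None or abs(offset5) <= tol5
        ok3 = offset3 is None or abs(offset3) <= tol3
        if ok5 and ok3:
            spec = "canonical"
        elif ok3:
            spec = "shifted_5prime"
        elif ok5:
            spec = "shifted_3prime"
        else:
            # both displaced: report the dominant side (5' on ties)
            spec = ("shifted_5prime"
                    if abs(offset5 or 0) >= abs(offset3 or 0) else "shifted_3prime")
            flags.append("both_junctions_shifted")
    return JunctionCall(copy_id=copy.copy_id, flank5_hit=hit5, flank3_hit=hit3,
                        offset5=offset5, offset3=offset3, specificity=spec,
                        flags=flags)


def classify_family(calls: list[JunctionCall],
                    specific_fraction: float = 0.9,
                    family_id: str = "family") -> FamilySpecificity:
    """Aggregate per-copy junction calls into a family-level verdict."""
    if not calls:
        raise ValueError("classify_family requires at least one call")
    n = len(calls)
    n_non = sum(c.specificity == "non_adjacent" for c in calls)
    n_adj = n - n_non
    if n_adj == 0:
        verdict = "non_specific"
    elif n_adj / n >= specific_fraction:
        verdict = "target_specific"
    else:
        verdict = "partially_specific"
    offsets = [c.offset5 for c in calls if c.offset5 is not None]
    modal = None
    if offsets:
        counts = Counter(offsets)
        top = max(counts.values())
        modal = min(o for o, c in counts.items() if c == top)  # ties -> smallest
    return FamilySpecificity(family_id=family_id, n_copies=n, n_adjacent=n_adj,
                             n_non_adjacent=n_non, verdict=verdict,
                             modal_offset5=modal)


def detect_target_like_utr(
    family: ElementFamily | str,
    target: TargetReference,
    flank_identity: float,
    min_hit_len: int = 30,
    utr_scan_len: int = 300,
    family_id: Optional[str] = None,
) -> UTRTargetMatch:
    """Screen the 3′ terminal region of a family consensus for a degraded
    target-gene segment.

    ``flank_identity`` is the observed identity of true downstream flanks to
    the target (measured from adjacent copies). A qualifying hit whose
    identity is strictly below it is called UTR-internal; a hit as good as
    the flanks cannot be distinguished from true flanking sequence.
    """
    if isinstance(family, ElementFamily):
        cons, fid = family.consensus, family.family_id
    else:
        cons, fid = family, (family_id or "family")
    if len(cons) < 500:
        raise ValueError("family consensus must be >= 500 bp")
    if min_hit_len < 30:
        raise ValueError("min_hit_len must be >= 30")
    utr = cons[-utr_scan_len:]
    # stricter scoring than the flank aligner: stops chance extension of the
    # alignment through random UTR sequence, which would dilute the identity
    # of an embedded segment (an exact segment must measure exactly 1.0)
    aln = local_align(utr, target.sequence, match=1.0, mismatch=-3.0,
                      gap_open=-5.0, gap_extend=-2.0)
    if aln.aligned_cols < min_hit_len:
        return UTRTargetMatch(family_id=fid, utr_interval=None,
                              target_interval=None, identity=None,
                              flank_identity=flank_identity,
                              is_utr_internal=False)
    off = len(cons) - len(utr)
    identity = aln.identity
    return UTRTargetMatch(
        family_id=fid,
        utr_interval=(off + aln.q_start, off + aln.q_end),
        target_interval=(aln.t_start, aln.t_end),
        identity=round(identity, 4),
        flank_identity=flank_identity,
        is_utr_internal=identity < flank_identity,
    )


def find_motif(seq: str, motif: str) -> list[tuple[int, int]]:
    """All exact occurrences of ``motif`` (U ≡ T), 1-based inclusive."""
    if not motif:
        raise ValueError("empty motif")
    s = seq.upper().replace("U", "T")
    m = motif.upper().replace("U", "T")
    out = []
    start = 0
    while True:
        i = s.find(m, start)
        if i < 0:
            break
        out.append((i + 1, i + len(m)))
        start = i + 1
    return out
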