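"""Affine-gap pairwise alignment (Gotoh dynamic programming).

Local (Smith–Waterman) alignment anchors junction flanks and 3′-UTR segments
on the target gene; global (Needleman–Wunsch) alignment backs pairwise
identity. Scoring defaults follow the package convention: match +1,
mismatch −1, and a gap of length L scores gap_open + L·gap_extend
(so a single-base gap costs 3 with the defaults).

Three states are tracked per cell: M (residue pair), IX (gap in the query,
consuming target) and IY (gap in the target, consuming query). Gaps open from
M only, so adjacent insertion/deletion columns never occur. Rows are updated
with numpy; the horizontal IX recurrence is closed into a prefix-maximum so
each row is fully vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NEG = -1e9


@dataclass
class Alignment:
    """One pairwise alignment with 0-based half-open end coordinates."""

    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    aligned_cols: int
    q_aln: str
    t_aln: str

    @property
    def identity(self) -> float:
        """Matches over aligned columns (dual-gap columns cannot occur)."""
        return self.matches / self.aligned_cols if self.aligned_cols else 0.0


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("latin1"), dtype=np.uint8)


def _fill(query, target, match, mismatch, gap_open, gap_extend, local):
    q = _encode(query)
    t = _encode(target)
    m, n = len(q), len(t)
    M = np.full((m + 1, n + 1), NEG)
    IX = np.full((m + 1, n + 1), NEG)
    IY = np.full((m + 1, n + 1), NEG)
    j_idx = np.arange(n + 1)
    if local:
        M[0, :] = 0.0
    else:
        M[0, 0] = 0.0
        IX[0, 1:] = gap_open + gap_extend * j_idx[1:]
    for i in range(1, m + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], IX[i - 1]), IY[i - 1])
        sub = np.where(t == q[i - 1], match, mismatch)
        row = best_prev[:-1] + sub
        if local:
            M[i, 1:] = np.maximum(row, 0.0)
            M[i, 0] = 0.0
        else:
            M[i, 1:] = row
        IY[i, :] = np.maximum(M[i - 1, :] + gap_open + gap_extend,
                              IY[i - 1, :] + gap_extend)
        if not local:
            IY[i, 0] = gap_open + gap_extend * i
        # IX[i,j] = max_{k<j} M[i,k] + gap_open + (j-k)*gap_extend
        c = np.maximum.accumulate(M[i, :] - gap_extend * j_idx)
        IX[i, 1:] = gap_open + gap_extend * j_idx[1:] + c[:-1]
        IX[i, 0] = NEG
    return q, t, M, IX, IY


def _traceback(q, t, M, IX, IY, i, j, match, mismatch, gap_open, gap_extend, local):
    qa: list[str] = []
    ta: list[str] = []
    matches = 0
    state = "M"
    if not local:
        end = max((M[i, j], "M"), (IX[i, j], "IX"), (IY[i, j], "IY"))
        state = end[1]
    eps = 1e-6
    while i > 0 or j > 0:
        if state == "M":
            if local and M[i, j] <= eps:
                break
            if i == 0 or j == 0:
                break
            s = match if q[i - 1] == t[j - 1] else mismatch
            if q[i - 1] == t[j - 1]:
                matches += 1
            qa.append(chr(q[i - 1]))
            ta.append(chr(t[j - 1]))
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            if local and prev <= eps:
                break
            if abs(M[i, j] - prev) < eps:
                state = "M"
            elif abs(IY[i, j] - prev) < eps:
                state = "IY"
            else:
                state = "IX"
        elif state == "IX":
            qa.append("-")
            ta.append(chr(t[j - 1]))
            if j >= 2 and abs(IX[i, j] - (IX[i, j - 1] + gap_extend)) < eps:
                j -= 1
            else:
                j -= 1
                state = "M"
        else:  # IY
            qa.append(chr(q[i - 1]))
            ta.append("-")
            if i >= 2 and abs(IY[i, j] - (IY[i - 1, j] + gap_extend)) < eps:
                i -= 1
            else:
                i -= 1
                state = "M"
        if local and state == "M" and M[i, j] <= eps:
            break
        if not local and i == 0 and j > 0:
            state = "IX"
        if not local and j == 0 and i > 0:
            state = "IY"
    return i, j, matches, "".join(reversed(qa)), "".join(reversed(ta))


def local_align(query: str, target: str, match: float = 1.0, mismatch: float = -1.0,
                gap_open: float = -2.0, gap_extend: float = -1.0) -> Alignment:
    """Best local alignment of ``query`` against ``target``."""
    if not query or not target:
        return Alignment(0.0, 0, 0, 0, 0, 0, 0, "", "")
    q, t, M, IX, IY = _fill(query, target, match, mismatch, gap_open, gap_extend, True)
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    score = float(M[i, j])
    if score <= 0:
        return Alignment(0.0, 0, 0, 0, 0, 0, 0, "", "")
    qe, te = int(i), int(j)
    qs, ts, matches, qa, ta = _traceback(q, t, M, IX, IY, qe, te, match, mismatch,
                                         gap_open, gap_extend, True)
    return Alignment(score, qs, qe, ts, te, matches, len(qa), qa, ta)


def global_align(query: str, target: str, match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -2.0, gap_extend: float = -1.0) -> Alignment:
    """End-to-end alignment of two non-empty sequences."""
    if not query or not target:
        raise ValueError("global_align requires non-empty sequences")
    q, t, M, IX, IY = _fill(query, target, match, mismatch, gap_open, gap_extend, False)
    m, n = len(q), len(t)
    score = float(max(M[m, n], IX[m, n], IY[m, n]))
    _, _, matches, qa, ta = _traceback(q, t, M, IX, IY, m, n, match, mismatch,
                                       gap_open, gap_extend, False)
    return Alignment(score, 0, m, 0, n, matches, len(qa), qa, ta)
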