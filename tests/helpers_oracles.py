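"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives the expected result by exhaustive enumeration or a
structurally different algorithm, so agreement is evidence of correctness of
the production code path, not a tautology.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def oracle_align_score(q: str, t: str, local: bool, match: float = 1.0,
                       mismatch: float = -1.0, gap_open: float = -2.0,
                       gap_extend: float = -1.0) -> float:
    """Full three-state DP computed with plain nested loops and explicit
    transition rules (gaps open from the match state only, as in the
    production aligner); returns the optimal score."""
    m, n = len(q), len(t)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    IX = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query
    IY = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in target
    if local:
        for j in range(n + 1):
            M[0][j] = 0.0
        for i in range(m + 1):
            M[i][0] = 0.0
    else:
        M[0][0] = 0.0
        for j in range(1, n + 1):
            IX[0][j] = gap_open + gap_extend * j
        for i in range(1, m + 1):
            IY[i][0] = gap_open + gap_extend * i
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if q[i - 1] == t[j - 1] else mismatch
            diag = max(M[i - 1][j - 1], IX[i - 1][j - 1], IY[i - 1][j - 1])
            val = diag + s if diag > NEG else NEG
            M[i][j] = max(0.0, val) if local else val
            IX[i][j] = max(M[i][j - 1] + gap_open + gap_extend,
                           IX[i][j - 1] + gap_extend)
            IY[i][j] = max(M[i - 1][j] + gap_open + gap_extend,
                           IY[i - 1][j] + gap_extend)
    if local:
        return max(M[i][j] for i in range(m + 1) for j in range(n + 1))
    return max(M[m][n], IX[m][n], IY[m][n])


def oracle_zinc_fingers(protein: str, region_end: int) -> list[tuple[str, int, int]]:
    """Enumerate every (c1, c2, h, x) index quadruple satisfying
    C-x(2,4)-C-x(8,20)-H-x(3,5)-[H|C], then apply greedy leftmost-minimal
    selection with resume-after-match."""
    region = protein[:region_end]
    quads = []
    for c1 in (i for i, a in enumerate(region) if a == "C"):
        for c2 in range(c1 + 3, c1 + 6):
            if c2 >= len(region) or region[c2] != "C":
                continue
            for h in range(c2 + 9, c2 + 22):
                if h >= len(region) or region[h] != "H":
                    continue
                for x in range(h + 4, h + 7):
                    if x < len(region) and region[x] in "HC":
                        quads.append((c1, c2, h, x))
    quads.sort()
    out = []
    resume = 0
    for c1, c2, h, x in quads:
        if c1 >= resume:
            kind = "CCHH" if region[x] == "H" else "CCHC"
            out.append((kind, c1, x + 1))
            resume = x + 1
    return out


def iupac_expand(code: str) -> set[str]:
    table = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
             "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT",
             "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT"}
    return set(table[code])


def oracle_iupac_match(primer: str, template: str, pos: int) -> bool:
    """Set-expansion semantics: a template base matches iff it is one of the
    concrete bases the primer code stands for; non-ACGT template characters
    match only by exact code identity."""
    for k, c in enumerate(primer):
        t = template[pos + k]
        if t in "ACGT":
            if t not in iupac_expand(c):
                return False
        elif t != c:
            return False
    return True


def oracle_virtual_pcr(template: str, fwd: str, rev: str, max_len: int):
    """Brute-force double loop over all primer sites on both orientations.
    Returns plus-strand (start, end, strand) triples."""
    from r2scan.io import revcomp

    out = []
    for strand in "+-":
        s = template if strand == "+" else revcomp(template)
        f_sites = [i for i in range(len(s) - len(fwd) + 1)
                   if oracle_iupac_match(fwd, s, i)]
        rc_rev = revcomp(rev)
        r_sites = [i for i in range(len(s) - len(rc_rev) + 1)
                   if oracle_iupac_match(rc_rev, s, i)]
        for f in f_sites:
            for r in r_sites:
                end = r + len(rev)
                if 0 < end - f <= max_len:
                    if strand == "+":
                        out.append((f, end, "+"))
                    else:
                        out.append((len(s) - end, len(s) - f, "-"))
    return sorted(out)


def random_additive_tree(rng, n_leaves: int):
    """Random binary tree with positive branch lengths; returns (labels,
    distance dict, bipartitions). Distances are exact path lengths, so NJ
    must recover the topology."""
    labels = [f"T{i}" for i in range(n_leaves)]
    # build by random sequential joining; track leaf-sets per internal edge
    import numpy as np

    nodes = {l: ([l], None) for l in labels}
    adj: dict[str, list[tuple[str, float]]] = {l: [] for l in labels}
    pool = list(labels)
    counter = itertools.count()
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[i], pool[j]
        new = f"I{next(counter)}"
        la, lb = rng.uniform(0.05, 1.0, size=2)
        adj.setdefault(new, [])
        adj[new] += [(a, la), (b, lb)]
        adj[a].append((new, la))
        adj[b].append((new, lb))
        pool = [p for p in pool if p not in (a, b)] + [new]
    a, b = pool
    l = float(rng.uniform(0.05, 1.0))
    adj[a].append((b, l))
    adj[b].append((a, l))

    def path_len(x, y):
        stack = [(x, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == y:
                return dist
            for nxt, w in adj[node]:
                if nxt != prev:
                    stack.append((nxt, dist + w, node))
        raise RuntimeError

    d = {(x, y): path_len(x, y) for x, y in itertools.combinations(labels, 2)}

    # bipartitions: for each internal edge, the leaf set on one side
    all_leaves = frozenset(labels)
    bips = set()
    for node, edges in adj.items():
        for nxt, _ in edges:
            side = _leaves_beyond(adj, nxt, node)
            if 1 < len(side) < len(labels) - 1:
                bips.add(min(frozenset(side), all_leaves - frozenset(side),
                             key=lambda s: (len(s), sorted(s))))
    return labels, d, bips


def _leaves_beyond(adj, start, blocked):
    out = []
    stack = [(start, blocked)]
    while stack:
        node, prev = stack.pop()
        kids = [n for n, _ in adj[node] if n != prev]
        if node.startswith("T"):
            out.append(node)
        for kid in kids:
            stack.append((kid, node))
    return out
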