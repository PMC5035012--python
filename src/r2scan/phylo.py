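"""Distance phylogeny: p-distance, neighbor-joining, column bootstrap.

The clade structure of R2 is tested here as distance-tree monophyly, not as
a maximum-likelihood reconstruction: p-distances between aligned RT-region
proteins feed a standard Saitou–Nei neighbor-joining agglomeration, and
edge support comes from resampling alignment columns with replacement.
Q-criterion ties are broken by the lexicographically smallest label pair, so
a tree is a deterministic function of its distance matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GAP_CHARS = set("-.?X")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("matrix must be symmetric with zero diagonal")


@dataclass
class TreeNode:
    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]
        out: list[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        sup = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){sup}"


@dataclass
class CladeTree:
    """Unrooted tree represented with an arbitrary internal node as root."""

    root: TreeNode
    labels: list[str]
    negative_lengths_clamped: int = 0

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted splits, each as its smaller/canonical side."""
        all_leaves = frozenset(self.labels)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if not node.children:
                return frozenset([node.label])
            below = frozenset()
            for c, _ in node.children:
                side = walk(c)
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(min(side, all_leaves - side,
                                key=lambda s: (len(s), sorted(s))))
                below |= side
            return below

        walk(self.root)
        return out

    def is_monophyletic(self, group: Sequence[str]) -> bool:
        """Do these leaves form a connected subtree of the unrooted tree?"""
        g = frozenset(group)
        if not g <= set(self.labels):
            raise ValueError("group contains unknown leaves")
        if len(g) <= 1 or len(g) >= len(self.labels) - 1:
            return True
        rest = frozenset(self.labels) - g
        canon = min(g, rest, key=lambda s: (len(s), sorted(s)))
        return canon in self.bipartitions()


def p_distance(rows: dict[str, str] | list[tuple[str, str]],
               deletion: str = "pairwise") -> DistanceMatrix:
    """Proportion-of-differences distance between aligned protein rows.

    ``deletion='complete'`` drops every column containing a gap/ambiguity in
    any row before counting; ``'pairwise'`` drops such columns per pair. A
    pair with no comparable columns raises, naming the pair.
    """
    items = list(rows.items()) if isinstance(rows, dict) else list(rows)
    if len(items) < 3:
        raise ValueError("p_distance needs at least 3 rows")
    labels = [n for n, _ in items]
    seqs = [s.upper() for _, s in items]
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("rows must have equal length")
    arr = np.array([list(s) for s in seqs])
    good = ~np.isin(arr, list(GAP_CHARS))
    if deletion == "complete":
        keep = good.all(axis=0)
        arr, good = arr[:, keep], good[:, keep]
    elif deletion != "pairwise":
        raise ValueError("deletion must be 'pairwise' or 'complete'")
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = good[i] & good[j]
        m = int(both.sum())
        if m == 0:
            raise ValueError(f"no comparable columns between "
                             f"{labels[i]!r} and {labels[j]!r}")
        diff = int((arr[i, both] != arr[j, both]).sum())
        d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(labels=labels, d=d)


def nj_tree(dm: DistanceMatrix) -> CladeTree:
    """Saitou–Nei neighbor joining; negative branch lengths clamp to 0."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("nj_tree needs at least 3 labels")
    nodes: dict[str, TreeNode] = {l: TreeNode(label=l) for l in dm.labels}
    # active distances keyed by node-key; node keys stay comparable strings
    d: dict[tuple[str, str], float] = {}
    active = list(dm.labels)
    for i, j in itertools.combinations(range(n), 2):
        d[_key(dm.labels[i], dm.labels[j])] = float(dm.d[i, j])
    clamped = 0
    counter = itertools.count()

    def dist(a: str, b: str) -> float:
        return d[_key(a, b)]

    while len(active) > 3:
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        m = len(active)
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * dist(a, b) - r[a] - r[b]
            if best is None or q < best[0] - 1e-12:
                best = (q, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            la, lb, clamped = 0.0, dab, clamped + 1
        if lb < 0:
            lb, la, clamped = 0.0, dab, clamped + 1
        new = f"__node{next(counter)}"
        nodes[new] = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        for c in active:
            if c in (a, b):
                continue
            d[_key(new, c)] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = sorted(set(active) - {a, b}) + [new]

    a, b, c = sorted(active)
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    lengths = []
    for l in (la, lb, lc):
        if l < 0:
            clamped += 1
            l = 0.0
        lengths.append(l)
    root = TreeNode(children=[(nodes[a], lengths[0]), (nodes[b], lengths[1]),
                              (nodes[c], lengths[2])])
    return CladeTree(root=root, labels=list(dm.labels),
                     negative_lengths_clamped=clamped)


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def bootstrap_support(rows: dict[str, str], n_reps: int = 100,
                      seed: int = 0, deletion: str = "pairwise") -> CladeTree:
    """NJ tree with per-edge column-bootstrap support (percent of replicates
    containing the same unrooted bipartition)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    items = list(rows.items())
    labels = [n for n, _ in items]
    width = len(items[0][1])
    tree = nj_tree(p_distance(rows, deletion))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        resampled = {n: "".join(s[c] for c in cols) for n, s in items}
        rep = nj_tree(p_distance(resampled, deletion))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    all_leaves = frozenset(labels)

    def annotate(node: TreeNode) -> frozenset[str]:
        below = frozenset()
        if not node.children:
            return frozenset([node.label])
        for c, _ in node.children:
            below |= annotate(c)
        if 1 < len(below) < len(all_leaves) - 1:
            canon = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            if canon in counts:
                node.support = 100.0 * counts[canon] / n_reps
        return below

    annotate(tree.root)
    return tree
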