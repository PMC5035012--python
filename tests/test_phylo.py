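"""p-distance, neighbor joining and bootstrap support."""

import itertools

import numpy as np
import pytest

from helpers_oracles import random_additive_tree
from r2scan.phylo import (DistanceMatrix, bootstrap_support, nj_tree,
                          p_distance)


class TestPDistance:
    def test_identical_rows_all_zero(self):
        dm = p_distance({"a": "AAAA", "b": "AAAA", "c": "AAAA"})
        assert np.all(dm.d == 0)

    def test_quarter_difference(self):
        dm = p_distance({"a": "AAAA", "b": "AAAT", "c": "TTTT"})
        assert dm.d[0, 1] == 0.25
        assert dm.d[0, 2] == 1.0

    def test_pairwise_vs_complete_deletion(self):
        rows = {"a": "AC-T", "b": "ACGT", "c": "TCGT"}
        pair = p_distance(rows, deletion="pairwise")
        comp = p_distance(rows, deletion="complete")
        assert pair.d[0, 1] == 0.0          # 3 comparable columns, 0 diffs
        assert pair.d[1, 2] == 0.25          # 4 columns, 1 diff
        assert comp.d[1, 2] == pytest.approx(1 / 3)  # gap column dropped for all

    def test_counting_oracle_on_random_alignments(self):
        rng = np.random.default_rng(8)
        alphabet = list("ACDEFG-")
        for _ in range(30):
            n, w = int(rng.integers(3, 11)), int(rng.integers(10, 51))
            rows = {f"s{i}": "".join(np.array(alphabet)[rng.integers(0, 7, w)])
                    for i in range(n)}
            dm = p_distance(rows, deletion="pairwise")
            names = list(rows)
            for i, j in itertools.combinations(range(n), 2):
                diffs = comp = 0
                for a, b in zip(rows[names[i]], rows[names[j]]):
                    if a != "-" and b != "-":
                        comp += 1
                        diffs += a != b
                assert dm.d[i, j] == pytest.approx(diffs / comp)

    def test_zero_comparable_columns_names_the_pair(self):
        with pytest.raises(ValueError, match="alpha.*beta"):
            p_distance({"alpha": "A---", "beta": "---T", "gamma": "ACGT"})

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            p_distance({"a": "AC", "b": "AC"})


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0.0]]))
        tree = nj_tree(dm)
        lengths = {c.label: bl for c, bl in tree.root.children}
        assert lengths["a"] == pytest.approx((4 + 6 - 8) / 2)  # 1
        assert lengths["b"] == pytest.approx((4 + 8 - 6) / 2)  # 3
        assert lengths["c"] == pytest.approx((6 + 8 - 4) / 2)  # 5

    def test_four_taxa_additive_recovery(self):
        # hand-drawn tree: (a,b) and (c,d) cherries joined by internal edge 2;
        # external edges a=1, b=3, c=2, d=4
        d = {("a", "b"): 4, ("a", "c"): 5, ("a", "d"): 7,
             ("b", "c"): 7, ("b", "d"): 9, ("c", "d"): 6}
        labels = ["a", "b", "c", "d"]
        mat = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            mat[i, j] = mat[j, i] = v
        tree = nj_tree(DistanceMatrix(labels, mat))
        assert tree.bipartitions() == {frozenset({"a", "b"})}
        # branch lengths are exact on additive input
        newick = tree.newick()
        for leaf, bl in (("a", 1), ("b", 3), ("c", 2), ("d", 4)):
            assert f"{leaf}:{bl:.6f}" in newick

    def test_random_additive_trees_recovered(self):
        """Additivity guarantees NJ recovers the generating topology."""
        rng = np.random.default_rng(55)
        for trial in range(20):
            n = int(rng.integers(5, 9))
            labels, d, bips = random_additive_tree(rng, n)
            mat = np.zeros((n, n))
            for (x, y), v in d.items():
                i, j = labels.index(x), labels.index(y)
                mat[i, j] = mat[j, i] = v
            tree = nj_tree(DistanceMatrix(labels, mat))
            assert tree.bipartitions() == bips, trial

    def test_matches_dendropy_topology(self):
        """Independent cross-check against dendropy's NJ on noisy distances."""
        import dendropy
        rng = np.random.default_rng(77)
        n = 8
        labels = [f"t{i}" for i in range(n)]
        base = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0.0)
        tree = nj_tree(DistanceMatrix(labels, mat))

        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(mat[i, j]) for j in range(n))
            for i in range(n))
        import io
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=",")
        dtree = pdm.nj_tree()
        dtree.encode_bipartitions()
        want = set()
        for bip in dtree.bipartition_encoding:
            leaves = frozenset(t.label
                               for t in bip.leafset_taxa(dtree.taxon_namespace))
            if 1 < len(leaves) < n - 1:
                want.add(min(leaves, frozenset(labels) - leaves,
                             key=lambda s: (len(s), sorted(s))))
        assert tree.bipartitions() == want

    def test_relabeling_permutes_topology_only(self):
        rng = np.random.default_rng(12)
        n = 6
        base = rng.uniform(0.1, 1.0, size=(n, n))
        mat = (base + base.T) / 2
        np.fill_diagonal(mat, 0.0)
        labels = [f"x{i}" for i in range(n)]
        t1 = nj_tree(DistanceMatrix(labels, mat))
        perm = rng.permutation(n)
        labels2 = [labels[i] for i in perm]
        t2 = nj_tree(DistanceMatrix(labels2, mat[np.ix_(perm, perm)]))
        assert t1.bipartitions() == t2.bipartitions()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, np.inf], [np.inf, 0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], np.zeros((2, 2)))


class TestBootstrap:
    def saturated_rows(self):
        # identical within clades, saturated between
        return {
            "a1": "A" * 30 + "C" * 30, "a2": "A" * 30 + "C" * 30,
            "a3": "A" * 30 + "C" * 30,
            "b1": "T" * 30 + "G" * 30, "b2": "T" * 30 + "G" * 30,
            "b3": "T" * 30 + "G" * 30,
            "c1": "G" * 30 + "A" * 30, "c2": "G" * 30 + "A" * 30,
        }

    def test_saturated_clades_get_full_support(self):
        tree = bootstrap_support(self.saturated_rows(), n_reps=50, seed=1)
        supports = _collect_supports(tree.root)
        assert supports and all(s == 100.0 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(2)
        rows = {f"s{i}": "".join(np.array(list("ACDE"))[rng.integers(0, 4, 40)])
                for i in range(6)}
        tree = bootstrap_support(rows, n_reps=1, seed=3)
        assert set(_collect_supports(tree.root)) <= {0.0, 100.0}

    def test_seed_stability_band(self):
        """Clade-edge supports from two seeds differ by a bounded amount."""
        from r2scan.syngenome import simulate_clade_protein_set
        rows = simulate_clade_protein_set(seed=5)
        t1 = bootstrap_support(rows, n_reps=100, seed=10)
        t2 = bootstrap_support(rows, n_reps=100, seed=20)
        s1 = _clade_supports(t1)
        s2 = _clade_supports(t2)
        for clade in s1:
            assert abs(s1[clade] - s2[clade]) <= 15


def _collect_supports(node):
    out = []
    if node.support is not None:
        out.append(node.support)
    for c, _ in node.children:
        out.extend(_collect_supports(c))
    return out


def _clade_supports(tree):
    """Support of the edge subtending each 3-leaf clade, if present."""
    out = {}

    def walk(node):
        leaves = frozenset(node.leaves())
        if node.support is not None and len(leaves) == 3:
            prefixes = {l.split("_")[0] for l in leaves}
            if len(prefixes) == 1:
                out[prefixes.pop()] = node.support
        for c, _ in node.children:
            walk(c)

    walk(tree.root)
    return out
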