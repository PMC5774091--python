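"""Progressive alignment, neighbor joining, bootstrap and subfamily calls."""

import itertools

import dendropy
import numpy as np
import pytest

from familyscan import phylogeny as ph
from familyscan import synthetic_data as sd
from familyscan.genome_io import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# oracles


def random_additive_matrix(n, seed):
    """Random binary tree -> (leaf distance matrix, bipartition set)."""
    rng = np.random.default_rng(seed)
    # start from a 3-leaf star, attach leaves to random edges
    nodes = {0: None}
    edges = []  # (child, parent, length)
    adj = {}

    def add_edge(a, b, ln):
        adj.setdefault(a, []).append((b, ln))
        adj.setdefault(b, []).append((a, ln))

    internal = ["i0"]
    for leaf in range(3):
        add_edge(leaf, "i0", float(rng.uniform(0.5, 2.0)))
    next_internal = 1
    for leaf in range(3, n):
        # split a random existing edge with a new internal node
        a, (b, ln) = None, (None, None)
        flat = [(x, y, l) for x in adj for (y, l) in adj[x] if str(x) < str(y)]
        x, y, l = flat[rng.integers(0, len(flat))]
        adj[x] = [(t, ll) for t, ll in adj[x] if t != y]
        adj[y] = [(t, ll) for t, ll in adj[y] if t != x]
        mid = f"i{next_internal}"
        next_internal += 1
        add_edge(x, mid, l / 2)
        add_edge(y, mid, l / 2)
        add_edge(leaf, mid, float(rng.uniform(0.5, 2.0)))
    # all-pairs leaf path lengths
    labels = [f"L{k}" for k in range(n)]
    d = np.zeros((n, n))
    for i in range(n):
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for j in range(n):
            d[i, j] = dist[j]
    # bipartitions: cut each internal-internal or internal edge
    splits = set()
    for x in adj:
        for y, _ in adj[x]:
            if str(x) < str(y):
                side = set()
                stack, seen = [x], {x, y}
                while stack:
                    u = stack.pop()
                    if isinstance(u, int):
                        side.add(labels[u])
                    for v, _ in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                if 1 < len(side) < n - 1:
                    canon = frozenset(side) if labels[0] not in side else \
                        frozenset(set(labels) - side)
                    splits.add(canon)
    return labels, d, splits


def tree_splits(tree):
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor, all_set = leaves[0], frozenset(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(below) < len(leaves) - 1:
            out.add(below if anchor not in below else all_set - below)
    return out


# ---------------------------------------------------------------------------
# progressive alignment


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        msa = ph.progressive_align(
            [SequenceRecord("a", "MKVLD"), SequenceRecord("b", "MKVLD")])
        assert msa.rows == {"a": "MKVLD", "b": "MKVLD"}

    def test_small_gap_case(self):
        # exhaustive NW on this case puts the single gap opposite the C
        msa = ph.progressive_align(
            [SequenceRecord("a", "ACD"), SequenceRecord("b", "AD")])
        assert msa.n_columns == 3 and msa.rows["b"] == "A-D"

    def test_ungap_recovers_inputs(self):
        rng = np.random.default_rng(11)
        seqs = [SequenceRecord(f"s{i}",
                               "".join(rng.choice(list(AA),
                                                  size=int(rng.integers(30, 60)))))
                for i in range(5)]
        msa = ph.progressive_align(seqs)
        for rec in seqs:
            assert msa.ungapped(rec.id) == rec.residues

    def test_single_sequence_is_error(self):
        with pytest.raises(ValueError):
            ph.progressive_align([SequenceRecord("a", "MKV")])


class TestPDistance:
    def test_small_cases(self):
        msa = ph.MultipleAlignment(rows={"a": "AAA", "b": "AAT", "c": "AAA"})
        dm = ph.p_distance(msa)
        i, j = dm.ids.index("a"), dm.ids.index("b")
        assert dm.d[i, j] == pytest.approx(1 / 3)
        assert dm.d[i, dm.ids.index("c")] == 0.0

    def test_no_comparable_columns_warns(self):
        msa = ph.MultipleAlignment(rows={"a": "AA--", "b": "--TT"})
        with pytest.warns(UserWarning):
            dm = ph.p_distance(msa)
        assert dm.d[0, 1] == 1.0


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = ph.DistanceMatrix(["A", "B", "C"],
                               np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = ph.neighbor_joining(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    @pytest.mark.parametrize("n,seed", [(5, 0), (5, 3), (6, 1), (6, 7)])
    def test_additive_matrix_recovered(self, n, seed):
        labels, d, true_splits = random_additive_matrix(n, seed)
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, d))
        assert tree_splits(tree) == true_splits

    def test_matches_independent_nj_implementation(self):
        # cross-check against scikit-bio's neighbor joining
        import skbio

        rng = np.random.default_rng(21)
        labels, d, _ = random_additive_matrix(6, 5)
        noisy = d + rng.uniform(0, 0.05, size=d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        ours = ph.neighbor_joining(ph.DistanceMatrix(labels, noisy))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=labels))
        their_tree = dendropy.Tree.get(data=str(theirs), schema="newick")
        assert tree_splits(ours) == tree_splits(their_tree)

    def test_ultrametric_matches_upgma_topology(self):
        # ((A,B),(C,D)) ultrametric heights; brute force over the 3
        # unrooted 4-taxon topologies picks the same split
        d = np.array([
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 4],
            [6, 6, 4, 0]], float)
        labels = ["A", "B", "C", "D"]
        tree = ph.neighbor_joining(ph.DistanceMatrix(labels, d))
        best_split = min(
            [frozenset({"A", "B"}), frozenset({"A", "C"}), frozenset({"A", "D"})],
            key=lambda s: d[labels.index("A"), labels.index(next(iter(s - {"A"})))])
        got = tree_splits(tree)
        assert got == {frozenset({"C", "D"})} or got == {best_split}

    def test_asymmetric_matrix_is_error(self):
        with pytest.raises(ValueError):
            ph.DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]], float))

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            ph.neighbor_joining(ph.DistanceMatrix(["a", "b"],
                                                  np.array([[0, 1], [1, 0]], float)))


# ---------------------------------------------------------------------------
# bootstrap


class TestBootstrap:
    def test_duplicated_sequences_full_support(self):
        rng = np.random.default_rng(2)
        base = "".join(rng.choice(list(AA), size=120))
        other1 = "".join(rng.choice(list(AA), size=120))
        other2 = "".join(rng.choice(list(AA), size=120))
        seqs = [SequenceRecord("t1", base), SequenceRecord("t2", base),
                SequenceRecord("o1", other1), SequenceRecord("o2", other2)]
        tree = ph.bootstrap_support(seqs, n_reps=50, seed=4)
        splits = ph._bipartitions(tree)
        twin = [n for s, n in splits.items()
                if s == frozenset({"t1", "t2"})
                or s == frozenset({"o1", "o2"})]
        assert twin and all(n.label == "100" for n in twin)

    def test_seed_determinism(self):
        records, _, _ = sd.simulate_labeled_family(
            n_subfamilies=2, n_outgroup_queries=0, seed=3)
        msa = ph.progressive_align(records)
        t1 = ph.bootstrap_support(None, n_reps=30, seed=9, msa=msa)
        t2 = ph.bootstrap_support(None, n_reps=30, seed=9, msa=msa)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_strong_signal_high_support(self):
        # low within-clade divergence: every true bipartition >= 90
        records, labels, _ = sd.simulate_labeled_family(
            n_subfamilies=2, refs_per_subfamily=2, queries_per_subfamily=0,
            n_outgroup_queries=0, within_divergence=0.03, seed=6)
        msa = ph.progressive_align(records)
        tree = ph.bootstrap_support(None, n_reps=100, seed=12, msa=msa)
        supports = [int(node.label) for node in ph._bipartitions(tree).values()]
        assert supports and min(supports) >= 90

    def test_bad_rep_count(self):
        with pytest.raises(ValueError):
            ph.bootstrap_support([], n_reps=0, seed=0)


# ---------------------------------------------------------------------------
# divergent-sequence exclusion


class TestFlagDivergent:
    def _homolog_set(self, seed=8, n=10):
        rng = np.random.default_rng(seed)
        base = "M" + "".join(rng.choice(list(AA), size=199))
        return [SequenceRecord(f"h{i}", sd._mutate_protein(rng, base, 0.1))
                for i in range(n)], rng

    def test_random_intruder_excluded(self):
        seqs, rng = self._homolog_set()
        seqs.append(SequenceRecord("intruder",
                                   "".join(rng.choice(list(AA), size=200))))
        msa = ph.progressive_align(seqs)
        excluded, new_msa = ph.flag_divergent(seqs, msa)
        assert excluded == ["intruder"]
        assert "intruder" not in new_msa.ids

    def test_homogeneous_set_untouched(self):
        seqs, _ = self._homolog_set()
        msa = ph.progressive_align(seqs)
        excluded, same = ph.flag_divergent(seqs, msa)
        assert excluded == [] and same is msa

    def test_zero_threshold_excludes_nothing(self):
        seqs, rng = self._homolog_set(n=4)
        seqs.append(SequenceRecord("odd", "".join(rng.choice(list(AA), size=200))))
        msa = ph.progressive_align(seqs)
        excluded, _ = ph.flag_divergent(seqs, msa, min_identity=0.0,
                                        min_aligned_fraction=0.0)
        assert excluded == []


# ---------------------------------------------------------------------------
# subfamily assignment


def newick_tree(text):
    return dendropy.Tree.get(data=text, schema="newick")


class TestAssignSubfamilies:
    def test_sister_reference_assigns(self):
        tree = newick_tree("((q:1,r1:1)100:1,(r2:1,r3:1)100:1,x:3);")
        labels = {"r1": "CI", "r2": "CII", "r3": "CII"}
        result = ph.assign_subfamilies(tree, labels)
        assert result["q"] == "CI" and result["x"] == "UNCLASSIFIED"
        assert result["r1"] == "CI"  # references keep their labels

    def test_mixed_clade_unclassified(self):
        tree = newick_tree("((q:1,(r1:1,r2:1)100:1)100:1,o1:2,o2:2);")
        result = ph.assign_subfamilies(tree, {"r1": "CI", "r2": "CII"})
        assert result["q"] == "UNCLASSIFIED"

    def test_low_support_unclassified(self):
        tree = newick_tree("((q:1,r1:1)30:1,(r2:1,r3:1)100:1,x:3);")
        result = ph.assign_subfamilies(tree, {"r1": "CI", "r2": "CII", "r3": "CII"})
        assert result["q"] == "UNCLASSIFIED"

    def test_no_references_all_unclassified(self):
        tree = newick_tree("((a:1,b:1):1,c:1,d:1);")
        result = ph.assign_subfamilies(tree, {})
        assert set(result.values()) == {"UNCLASSIFIED"}

    def test_only_reference_labels_ever_assigned(self):
        records, labels, _ = sd.simulate_labeled_family(seed=2)
        msa = ph.progressive_align(records)
        tree = ph.bootstrap_support(None, n_reps=20, seed=2, msa=msa)
        result = ph.assign_subfamilies(tree, labels)
        allowed = set(labels.values()) | {"UNCLASSIFIED"}
        assert set(result.values()) <= allowed

    def test_planted_labels_recovered(self):
        records, labels, truth = sd.simulate_labeled_family(seed=1)
        msa = ph.progressive_align(records)
        tree = ph.bootstrap_support(None, n_reps=100, seed=11, msa=msa)
        result = ph.assign_subfamilies(tree, labels)
        assert {q: result[q] for q in truth} == truth
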