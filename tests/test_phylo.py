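"""p-distances, NJ reconstruction and subfamily assignment."""

import io

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from genefam.phylo import (
    DistanceMatrix,
    assign_subfamilies,
    bootstrap_splits,
    nj_tree,
    p_distance,
)
from genefam.synthetic_data import simulate_subfamilies


def _parse(newick):
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


def _splits(newick):
    tree = _parse(newick)
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips():
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(tips) - 1:
            side = min(clade, tips - clade, key=lambda s: sorted(s))
            out.add(side)
    return out


def _random_additive_matrix(rng, n_taxa):
    """Distances from a random binary tree with positive branch lengths."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [(lab,) for lab in labels]
    children: dict = {}
    lengths: dict = {}
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = a + b
        children[parent] = (a, b)
        lengths[a] = float(rng.uniform(0.05, 1.0))
        lengths[b] = float(rng.uniform(0.05, 1.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    # path lengths tip-to-tip
    paths = {}

    def walk(node, depth, acc):
        if len(node) == 1:
            acc[node[0]] = depth
            return
        for child in children[node]:
            walk(child, depth + lengths[child], acc)

    depths_from = {}
    for lab in labels:
        # distance via LCA: compute depth profiles from the root once
        pass
    acc = {}
    walk(root, 0.0, acc)

    def tip_set(node):
        return set(node)

    d = np.zeros((n_taxa, n_taxa))
    # distance(a,b) = depth(a) + depth(b) - 2*depth(lca)
    depth_of_node = {root: 0.0}
    stack = [root]
    while stack:
        node = stack.pop()
        for child in children.get(node, ()):
            depth_of_node[child] = depth_of_node[node] + lengths[child]
            stack.append(child)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            lca = max(
                (node for node in depth_of_node if a in node and b in node),
                key=lambda n: depth_of_node[n],
            )
            d[i, j] = d[j, i] = acc[a] + acc[b] - 2 * depth_of_node[lca]
    return DistanceMatrix(tuple(labels), d), children, root


class TestPDistance:
    def test_identical_and_disjoint(self):
        dm = p_distance({"a": "AAAA", "b": "AAAT", "c": "TTTT"})
        i = {lab: k for k, lab in enumerate(dm.labels)}
        assert dm.values[i["a"], i["a"]] == 0.0
        assert dm.values[i["a"], i["b"]] == 0.25
        assert dm.values[i["a"], i["c"]] == 1.0

    def test_gap_columns_excluded(self):
        dm = p_distance({"a": "AA--", "b": "AT-T"})
        assert dm.values[0, 1] == 0.5  # 2 shared columns, 1 mismatch

    def test_no_shared_columns_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            p_distance({"a": "AA--", "b": "--TT"})

    def test_ragged_rejected(self):
        with pytest.raises(ValueError):
            p_distance({"a": "AAA", "b": "AA"})


class TestNjTree:
    def test_four_taxon_additive_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) → pairwise path-length matrix
        labels = ("A", "B", "C", "D")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        newick = nj_tree(DistanceMatrix(labels, d))
        assert _splits(newick) == {frozenset({"A", "B"})}
        tree = _parse(newick)
        for a, b, want in (("A", "B", 3), ("A", "C", 5), ("B", "D", 7), ("C", "D", 7)):
            got = tree.find(a).distance(tree.find(b))
            assert got == pytest.approx(want)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        newick = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        tree = _parse(newick)
        assert tree.find("a").length == pytest.approx(0.0)
        assert tree.find("b").length == pytest.approx(2.0)
        assert tree.find("c").length == pytest.approx(3.0)

    def test_identical_rows_give_zero_cherry(self):
        d = np.array(
            [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        newick = nj_tree(DistanceMatrix(("a", "b", "c", "d"), d))
        tree = _parse(newick)
        assert tree.find("a").distance(tree.find("b")) == pytest.approx(0.0)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0]], float)))

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b", "c"),
                           np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))

    def test_newick_reparses_with_nonnegative_lengths(self, rng):
        dm, _, _ = _random_additive_matrix(rng, 8)
        tree = _parse(nj_tree(dm))
        assert {t.name for t in tree.tips()} == set(dm.labels)
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0

    def test_additive_matrices_recover_topology(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 13))
            dm, _, _ = _random_additive_matrix(rng, n)
            tree = _parse(nj_tree(dm))
            for i, a in enumerate(dm.labels):
                for j, b in enumerate(dm.labels):
                    if i < j:
                        assert tree.find(a).distance(tree.find(b)) == pytest.approx(
                            dm.values[i, j], abs=1e-8
                        )

    def test_matches_skbio_nj_topology(self, rng):
        dm, _, _ = _random_additive_matrix(rng, 9)
        mine = _splits(nj_tree(dm))
        reference = skbio_nj(SkbioDM(dm.values, ids=list(dm.labels)))
        theirs = _splits(str(reference).strip())
        assert mine == theirs

    def test_label_permutation_only_permutes_labels(self, rng):
        dm, _, _ = _random_additive_matrix(rng, 7)
        perm = list(rng.permutation(len(dm.labels)))
        relabel = {dm.labels[k]: f"z{i}" for i, k in enumerate(perm)}
        dm2 = DistanceMatrix(
            tuple(relabel[l] for l in dm.labels), dm.values
        )
        s1 = {frozenset(relabel[x] for x in split) for split in _splits(nj_tree(dm))}
        tips = frozenset(relabel.values())
        s1 = {min(s, tips - s, key=lambda s_: sorted(s_)) for s in s1}
        assert s1 == _splits(nj_tree(dm2))


class TestAssignSubfamilies:
    def test_query_sister_to_single_reference(self):
        newick = "((q:0.1,Cref:0.1):0.5,(Mref:0.1,x:0.9):0.5,o:1.0);"
        out = assign_subfamilies(newick, {"Cref": "C", "Mref": "M"})
        assert out["q"] == "C"

    def test_tie_gives_unassigned(self):
        newick = "((q:0.1,(Cref:0.1,Mref:0.1):0.05):0.5,a:1.0,b:1.2);"
        out = assign_subfamilies(newick, {"Cref": "C", "Mref": "M"})
        assert out["q"] == "unassigned"

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            assign_subfamilies("(a:1,b:1,c:1);", {"zz": "C"})

    def test_forged_subfamilies_fully_recovered(self):
        aln, refs, queries = simulate_subfamilies(rng_seed=11)
        newick = nj_tree(p_distance(aln))
        assigned = assign_subfamilies(newick, refs)
        assert all(assigned[q] == label for q, label in queries.items())


class TestBootstrap:
    def test_clean_subfamily_splits_have_high_support(self):
        aln, refs, queries = simulate_subfamilies(rng_seed=2, n_refs=2, n_queries=1)
        support = bootstrap_splits(aln, n_replicates=30, rng_seed=0)
        families = {}
        for name in aln:
            families.setdefault(name.split("_")[0], set()).add(name)
        for members in families.values():
            split = frozenset(members)
            if split in support:
                assert support[split] > 0.5
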