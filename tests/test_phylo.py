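"""Synonymous distances, NJ reconstruction, bootstrap and Newick output."""

import numpy as np
import pytest

from lucfam import phylo
from lucfam.phylo import (DistanceMatrix, PhyloTree, TreeNode,
                          bootstrap_support, nj_tree, syn_distance_matrix,
                          write_newick)

from util import make_mask, tree_path_lengths


class TestSynDistance:
    def test_identical_pair(self):
        mask = make_mask(30, [(1, 30)])
        dm = syn_distance_matrix(["GGG" * 10] * 2, ["a", "b"], mask)
        assert dm.matrix[0, 1] == 0.0

    def test_gamma_corrected_p03(self):
        """p_S = 0.3 maps to d = p/(1 - 4p/3) = 0.5 at gamma shape 1."""
        mask = make_mask(30, [(1, 30)])
        a = "GGG" * 10
        b = "GGA" * 3 + "GGG" * 7       # 3 synonymous diffs over 10 syn sites
        dm = syn_distance_matrix([a, b], ["a", "b"], mask)
        assert dm.matrix[0, 1] == pytest.approx(0.5, rel=1e-9)

    def test_saturated_entry_flagged(self):
        mask = make_mask(9, [(1, 9)])
        dm = syn_distance_matrix(["GGG" * 3, "GGA" * 3], ["a", "b"], mask)
        assert dm.undefined[0, 1]
        assert dm.undefined_pairs() == [("a", "b")]

    def test_family_ordering(self, two_family_truth):
        """Between-family synonymous distances exceed within-family ones."""
        truth = two_family_truth
        from lucfam.core import SeqRecord, anchor_align, build_site_mask
        ref = SeqRecord(id="r", nucleotides=truth.family_founders["F1"],
                        evidence_source="REF")
        aln = anchor_align([SeqRecord(id=h.name, nucleotides=h.sequence)
                            for h in truth.haplotypes], ref, free_end_gaps=False)
        mask = build_site_mask(aln, truth.annotation)
        rows = [m.nucleotides for m in aln.members]
        labels = [h.name for h in truth.haplotypes]
        dm = syn_distance_matrix(rows, labels, mask)
        within = [dm.matrix[i, j] for i in range(3) for j in range(i + 1, 3)]
        within += [dm.matrix[i, j] for i in range(3, 6) for j in range(i + 1, 6)]
        between = [dm.matrix[i, j] for i in range(3) for j in range(3, 6)]
        assert min(between) > max(within)


def _dm(labels, rows):
    return DistanceMatrix(labels=list(labels), matrix=np.array(rows, dtype=float))


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = _dm("abc", [[0, 3, 5], [3, 0, 6], [5, 6, 0]])
        tree = nj_tree(dm)
        lengths = {lf.label: lf.length for lf in tree.root.leaves()}
        assert lengths == {"a": pytest.approx(1.0), "b": pytest.approx(2.0),
                           "c": pytest.approx(4.0)}

    def test_four_taxon_additive(self):
        """Additive matrix from ((A:1,B:2):1,(C:3,D:4)): split AB|CD with
        exact path lengths."""
        labels = ["A", "B", "C", "D"]
        dm = _dm(labels, [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]])
        tree = nj_tree(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        D = tree_path_lengths(tree.root, labels)
        assert np.allclose(D, dm.matrix)

    def test_random_additive_trees_recovered(self):
        """NJ reproduces random additive trees (topology and path lengths)."""
        rng = np.random.default_rng(42)
        for trial in range(8):
            n = int(rng.integers(4, 13))
            labels = [f"t{i}" for i in range(n)]
            # random binary tree by sequential joining
            nodes = [TreeNode(label=lb) for lb in labels]
            while len(nodes) > 3:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                a, b = nodes[j], nodes[i]
                for x in (a, b):
                    x.length = float(rng.uniform(0.1, 1.0))
                nodes = [x for k, x in enumerate(nodes) if k not in (i, j)]
                nodes.append(TreeNode(children=[b, a]))
            for x in nodes:
                x.length = float(rng.uniform(0.1, 1.0))
            true_tree = PhyloTree(root=TreeNode(children=nodes), labels=labels)
            D = tree_path_lengths(true_tree.root, labels)
            got = nj_tree(DistanceMatrix(labels=labels, matrix=D))
            assert got.bipartitions() == true_tree.bipartitions()
            assert np.allclose(tree_path_lengths(got.root, labels), D, atol=1e-9)

    def test_agrees_with_scikit_bio(self):
        """Independent cross-check of topology against scikit-bio's NJ."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(7)
        nodes = [TreeNode(label=lb, length=float(rng.uniform(0.2, 1.0)))
                 for lb in labels]
        inner = TreeNode(children=nodes[:2], length=0.7)
        inner2 = TreeNode(children=[inner, nodes[2]], length=0.4)
        root = TreeNode(children=[inner2, nodes[3], nodes[4]])
        D = tree_path_lengths(root, labels)
        ours = nj_tree(DistanceMatrix(labels=labels, matrix=D))
        sk = skbio_nj(SkbioDM(D, ids=labels))
        ref = labels[0]
        sk_splits = set()
        for node in sk.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(labels) - 2:
                if ref in side:
                    side = frozenset(set(labels) - side)
                sk_splits.add(side)
        assert ours.bipartitions() == sk_splits

    def test_star_matrix_deterministic(self):
        dm1 = _dm("abcd", (np.ones((4, 4)) - np.eye(4)).tolist())
        dm2 = _dm("abcd", (np.ones((4, 4)) - np.eye(4)).tolist())
        assert write_newick(nj_tree(dm1)) == write_newick(nj_tree(dm2))

    def test_negative_branch_clamped(self):
        dm = _dm("abcd", [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 0.5], [4, 4, 0.5, 0]])
        tree = nj_tree(dm)
        for node, _ in phylo._walk_edges(tree.root):
            assert node.length >= 0.0

    def test_undefined_entries_rejected(self):
        dm = _dm("abc", [[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        dm.undefined[0, 1] = dm.undefined[1, 0] = True
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(dm)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(_dm("ab", [[0, 1], [1, 0]]))


def _bootstrap_fixture():
    """Two clearly separated synonymous-divergence groups of 3 sequences."""
    rng = np.random.default_rng(12)
    from lucfam import _codon
    n_cod = 120
    base = [_codon.SENSE_CODONS[i] for i in rng.integers(0, 61, n_cod)]

    def syn_mutate(codons, n_mut, rng):
        out = list(codons)
        tries = 0
        done = 0
        while done < n_mut and tries < 10000:
            tries += 1
            ci = int(rng.integers(n_cod))
            cod = out[ci]
            alts = [cod[:j] + b + cod[j + 1:] for j in range(3) for b in "ACGT"
                    if b != cod[j]]
            alts = [a for a in alts if a in _codon.AA
                    and _codon.AA[a] == _codon.AA[cod]]
            if not alts:
                continue
            out[ci] = alts[int(rng.integers(len(alts)))]
            done += 1
        return out

    g1_anc = syn_mutate(base, 40, rng)
    g2_anc = syn_mutate(base, 40, rng)
    rows, labels = [], []
    for g, anc in (("x", g1_anc), ("y", g2_anc)):
        for i in range(3):
            rows.append("".join(syn_mutate(anc, 6, rng)))
            labels.append(f"{g}{i}")
    mask = make_mask(3 * n_cod, [(1, 3 * n_cod)])
    return rows, labels, mask


class TestBootstrap:
    def test_family_split_strongly_supported(self):
        rows, labels, mask = _bootstrap_fixture()
        tree = bootstrap_support(rows, labels, mask, B=100, seed=3)
        split = frozenset({"y0", "y1", "y2"})
        supports = {frozenset(set(labels) - set(n.leaf_labels()))
                    if labels[0] in n.leaf_labels() else frozenset(n.leaf_labels()):
                    n.support
                    for n, _ in phylo._walk_edges(tree.root) if not n.is_leaf}
        assert supports.get(split, 0) >= 95

    def test_single_replicate_supports_binary(self):
        rows, labels, mask = _bootstrap_fixture()
        tree = bootstrap_support(rows, labels, mask, B=1, seed=5)
        for node, _ in phylo._walk_edges(tree.root):
            if node.support is not None:
                assert node.support in (0.0, 100.0)

    def test_fixed_seed_reproducible(self):
        rows, labels, mask = _bootstrap_fixture()
        t1 = bootstrap_support(rows, labels, mask, B=30, seed=9)
        t2 = bootstrap_support(rows, labels, mask, B=30, seed=9)
        assert write_newick(t1) == write_newick(t2)


class TestNewick:
    def test_round_trip_through_dendropy(self):
        import dendropy
        dm = _dm("abc", [[0, 3, 5], [3, 0, 6], [5, 6, 0]])
        text = write_newick(nj_tree(dm))
        tree = dendropy.Tree.get(data=text, schema="newick")
        assert {t.taxon.label for t in tree.leaf_node_iter()} == {"a", "b", "c"}
        total = sum(e.length for e in tree.edges() if e.length)
        assert total == pytest.approx(7.0)

    def test_supports_only_when_computed(self):
        dm = _dm("abcd", [[0, 2, 5, 6], [2, 0, 5, 6], [5, 5, 0, 3], [6, 6, 3, 0]])
        text = write_newick(nj_tree(dm))
        assert ")100" not in text and ")0:" not in text

    def test_labels_with_spaces_quoted(self):
        dm = _dm(["t a", "t b", "t c"], [[0, 3, 5], [3, 0, 6], [5, 6, 0]])
        text = write_newick(nj_tree(dm))
        assert "'t a'" in text
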