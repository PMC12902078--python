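"""Synonymous-distance matrices, Neighbor-Joining, bootstrap, Newick output.

Distances are synonymous p-distances under the transition/transversion-
weighted (R = 2) Nei-Gojobori site counting, corrected with a gamma-rate
Jukes-Cantor transform (shape a = 1), matching the convention of building
gene-family trees from synonymous sites only when introns are unalignable
across families.  The tree is unrooted; NJ uses the Studier-Keppler form
of the Q criterion with ties broken toward the lowest-index pair, and
negative branch lengths clamped to zero (deficit logged on the node).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _codon
from .core import SiteClassMask
from .popgen import SaturationError, gamma_correct

_ACGT = frozenset("ACGT")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray                 # symmetric, zero diagonal
    undefined: np.ndarray | None = None  # boolean mask of saturated entries

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.undefined is None:
            self.undefined = np.zeros_like(self.matrix, dtype=bool)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                if self.undefined[i, j]:
                    out.append((self.labels[i], self.labels[j]))
        return out


@dataclass
class TreeNode:
    """Node of an (un)rooted phylogeny; the NJ result has a trifurcating root."""

    label: str | None = None
    length: float = 0.0
    support: float | None = None       # bootstrap %, internal edges only
    children: list["TreeNode"] = field(default_factory=list)
    clamped_deficit: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.leaves()]


@dataclass
class PhyloTree:
    root: TreeNode
    labels: list[str]
    n_bootstrap: int = 0
    n_skipped_replicates: int = 0

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial splits, each canonicalized as the side not holding labels[0]."""
        full = set(self.labels)
        ref = self.labels[0]
        out = set()
        for node, _parent in _walk_edges(self.root):
            side = set(node.leaf_labels())
            if len(side) < 2 or len(side) > len(full) - 2:
                continue
            if ref in side:
                side = full - side
            out.add(frozenset(side))
        return out


def _walk_edges(root: TreeNode):
    stack = [(c, root) for c in root.children]
    while stack:
        node, parent = stack.pop()
        yield node, parent
        stack.extend((c, node) for c in node.children)


# ---------------------------------------------------------------------------
# distances

def _pair_syn_p(codons_a: np.ndarray, codons_b: np.ndarray,
                S: np.ndarray, SD: np.ndarray) -> float | None:
    ok = (codons_a >= 0) & (codons_b >= 0)
    if not ok.any():
        return None
    a, b = codons_a[ok], codons_b[ok]
    sites = 0.5 * float(S[a].sum() + S[b].sum())
    if sites <= 0:
        return None
    return float(SD[a, b].sum()) / sites


def syn_distance_matrix(rows: list[str], labels: list[str], mask: SiteClassMask,
                        R: float = 2.0, gamma_a: float = 1.0,
                        codon_columns: list[tuple[int, int, int]] | None = None
                        ) -> DistanceMatrix:
    """Pairwise synonymous distances gamma_correct(p_S, a) with weighted sites.

    Pairwise deletion: a codon is used for a pair when both members carry
    plain-ACGT sense codons there.  Saturated pairs are flagged undefined.
    """
    cols = codon_columns if codon_columns is not None else mask.codon_columns
    S = _codon.syn_sites_array("weighted", R)
    SD, _ = _codon.diff_arrays()
    idx = np.array([
        [_codon.CODON_INDEX.get("".join(r[c] for c in cc), -1) for cc in cols]
        for r in rows], dtype=np.int64)
    n = len(rows)
    D = np.zeros((n, n))
    undef = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            p = _pair_syn_p(idx[i], idx[j], S, SD)
            if p is None:
                undef[i, j] = undef[j, i] = True
                continue
            try:
                D[i, j] = D[j, i] = gamma_correct(p, gamma_a)
            except SaturationError:
                undef[i, j] = undef[j, i] = True
    return DistanceMatrix(labels=list(labels), matrix=D, undefined=undef)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining (Studier-Keppler Q), deterministic ties.

    Requires >= 3 taxa and no undefined entries.  Negative branch lengths
    are clamped to zero with the deficit recorded on the node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    if dm.undefined is not None and dm.undefined.any():
        raise ValueError(f"undefined distance entries: {dm.undefined_pairs()}")
    D = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=lb) for lb in dm.labels]
    active = list(range(n))

    def clamp(node: TreeNode, length: float) -> None:
        if length < 0:
            node.clamped_deficit = -length
            node.length = 0.0
        else:
            node.length = float(length)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:  # strict improvement => lowest-index tie-break
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        clamp(nodes[i], li)
        clamp(nodes[j], lj)
        # distances from the new node
        new = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[new, k] = D[k, new] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new]

    i, j, k = active
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    clamp(nodes[i], 0.5 * (D[i, j] + D[i, k] - D[j, k]))
    clamp(nodes[j], 0.5 * (D[i, j] + D[j, k] - D[i, k]))
    clamp(nodes[k], 0.5 * (D[i, k] + D[j, k] - D[i, j]))
    return PhyloTree(root=root, labels=list(dm.labels))


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(rows: list[str], labels: list[str], mask: SiteClassMask,
                      B: int = 1000, seed: int = 0,
                      R: float = 2.0, gamma_a: float = 1.0) -> PhyloTree:
    """NJ tree with bootstrap supports from codon-column resampling.

    Codon columns (the only columns entering synonymous distances) are
    resampled with replacement; replicates yielding a saturated or
    undefined matrix are skipped and counted.
    """
    base_dm = syn_distance_matrix(rows, labels, mask, R=R, gamma_a=gamma_a)
    tree = nj_tree(base_dm)
    orig_splits = tree.bipartitions()
    counts = {sp: 0 for sp in orig_splits}
    rng = np.random.default_rng(seed)
    n_cod = len(mask.codon_columns)
    used = 0
    skipped = 0
    for _ in range(B):
        pick = rng.integers(0, n_cod, size=n_cod)
        cols = [mask.codon_columns[i] for i in pick]
        dm = syn_distance_matrix(rows, labels, mask, R=R, gamma_a=gamma_a,
                                 codon_columns=cols)
        if dm.undefined.any():
            skipped += 1
            continue
        rep_splits = nj_tree(dm).bipartitions()
        used += 1
        for sp in orig_splits & rep_splits:
            counts[sp] += 1
    for node, _parent in _walk_edges(tree.root):
        if node.is_leaf:
            continue
        side = set(node.leaf_labels())
        full = set(labels)
        if len(side) < 2 or len(side) > len(full) - 2:
            continue
        key = frozenset(full - side) if labels[0] in side else frozenset(side)
        if used > 0:
            node.support = 100.0 * counts[key] / used
    tree.n_bootstrap = used
    tree.n_skipped_replicates = skipped
    return tree


# ---------------------------------------------------------------------------
# newick

def _quote(label: str) -> str:
    if any(ch in label for ch in " \t()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: TreeNode, with_length: bool = True) -> str:
    if node.is_leaf:
        s = _quote(node.label or "")
    else:
        s = "(" + ",".join(_newick_node(c, with_length) for c in node.children) + ")"
        if node.support is not None:
            s += str(int(round(node.support)))
    if with_length:
        s += f":{node.length:.6g}"
    return s


def write_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths and integer supports on internal nodes."""
    inner = ",".join(_newick_node(c) for c in tree.root.children)
    return f"({inner});"
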