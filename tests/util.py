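"""Shared test helpers: direct mask construction and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

from lucfam.core import SiteClassMask

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


def make_mask(length: int, exons: list[tuple[int, int]],
              excluded: tuple[tuple[int, int], ...] = ()) -> SiteClassMask:
    """SiteClassMask for an ungapped alignment (column i == position i+1)."""
    cls = np.full(length, SiteClassMask.EXCLUDED, dtype=np.int8)
    excl = {p for s, e in excluded for p in range(s, e + 1)}
    exon_pos = [p for s, e in exons for p in range(s, e + 1)]
    for p in range(1, length + 1):
        if p in excl:
            continue
        cls[p - 1] = (SiteClassMask.CODING if p in set(exon_pos)
                      else SiteClassMask.NONCODING)
    codon_columns = []
    for i in range(0, len(exon_pos) - 2, 3):
        triple = exon_pos[i:i + 3]
        if any(p in excl for p in triple):
            continue
        codon_columns.append(tuple(p - 1 for p in triple))
    noncoding = np.array([p - 1 for p in range(1, length + 1)
                          if cls[p - 1] == SiteClassMask.NONCODING], dtype=np.int64)
    return SiteClassMask(col_class=cls, codon_columns=codon_columns,
                         noncoding_columns=noncoding)


# --- independent brute-force oracles ---------------------------------------

def brute_force_site_counts(codon: str, scheme: str = "unweighted", R: float = 2.0):
    """Synonymous site count by direct enumeration of all 9 point changes."""
    s = 0.0
    for j in range(3):
        syn_w = tot_w = 0.0
        for b in "ACGT":
            if b == codon[j]:
                continue
            alt = codon[:j] + b + codon[j + 1:]
            ts = frozenset((codon[j], b)) in ({frozenset("AG"), frozenset("CT")})
            w = R if (scheme == "weighted" and ts) else 1.0
            tot_w += w
            if alt not in _STOPS and _AA[alt] == _AA[codon]:
                syn_w += w
        s += syn_w / tot_w
    return s, 3.0 - s


def brute_force_diff_counts(a: str, b: str):
    """Pathway enumeration of synonymous/nonsynonymous differences."""
    diff = [j for j in range(3) if a[j] != b[j]]
    if not diff:
        return 0.0, 0.0
    syn_counts = []
    for order in itertools.permutations(diff):
        cur, syn, ok = a, 0, True
        for j in order:
            nxt = cur[:j] + b[j] + cur[j + 1:]
            if nxt in _STOPS:
                ok = False
                break
            if _AA[nxt] == _AA[cur]:
                syn += 1
            cur = nxt
        if ok:
            syn_counts.append(syn)
    if not syn_counts:
        return 0.0, float(len(diff))
    sd = sum(syn_counts) / len(syn_counts)
    return sd, len(diff) - sd


def interval_union_size(intervals: list[tuple[int, int]]) -> int:
    return len({p for s, e in intervals for p in range(s, e + 1)})


def tree_path_lengths(root, labels: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix of a lucfam TreeNode tree."""
    n = len(labels)
    idx = {lb: i for i, lb in enumerate(labels)}
    D = np.zeros((n, n))

    def below(node):
        """list of (leaf index, distance up to `node`)."""
        if node.is_leaf:
            return [(idx[node.label], 0.0)]
        sets = [[(i, d + ch.length) for i, d in below(ch)] for ch in node.children]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i, di in sets[a]:
                    for j, dj in sets[b]:
                        D[i, j] = D[j, i] = di + dj
        return [pair for s in sets for pair in s]

    below(root)
    return D


def splice_test_sequence():
    """A sequence with exactly 2 GT donors and 3 AG acceptors near the
    expected intron boundaries, all combinations frame-preserving and
    stop-free.  Returns (seq, expected_donor, expected_acceptor)."""
    exon1 = "GGC" * 10                       # no GT/AG dinucleotides
    intron = "GTC" + "GTC" + "C" * 12 + "AGCAGCAG"   # GT at +0,+3; AG at -8,-5,-2
    exon2 = "GGC" * 10
    seq = exon1 + intron + exon2
    expected_donor = len(exon1) + 1                   # GT start, 1-based
    expected_acceptor = len(exon1) + len(intron) - 1  # AG start, 1-based
    return seq, expected_donor, expected_acceptor
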