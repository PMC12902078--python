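"""Codon tables and Nei-Gojobori style site/difference counting primitives.

Precomputes, for all 61 sense codons, the fractional numbers of synonymous
and nonsynonymous sites (unweighted and transition/transversion-weighted
schemes) and, for all 61x61 codon pairs, pathway-averaged synonymous and
nonsynonymous difference counts.  Mutations that would create a stop codon
are treated as nonsynonymous when counting sites, and mutational pathways
passing through a stop codon are discarded when counting differences.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

BASES = "ACGT"
STOP_CODONS = frozenset(_TABLE.stop_codons)
AA = dict(_TABLE.forward_table)  # sense codons only

SENSE_CODONS = tuple(sorted(AA))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(b1: str, b2: str) -> bool:
    return (b1, b2) in _TRANSITIONS


def ng_site_counts(codon: str, scheme: str = "unweighted", R: float = 2.0):
    """Fractional (synonymous, nonsynonymous) site counts for one codon.

    ``unweighted``: at each position the synonymous fraction is the share of
    the three possible changes that preserve the amino acid.  ``weighted``:
    each change is weighted ``R`` if it is a transition and 1 otherwise
    (the "modified" counting with transition/transversion bias).  Changes
    creating stop codons count as nonsynonymous.  s + n == 3 by construction.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    if codon not in AA:
        raise ValueError(f"not a sense codon: {codon!r}")
    if scheme not in ("unweighted", "weighted"):
        raise ValueError(f"unknown scheme {scheme!r}")
    s = 0.0
    for j in range(3):
        syn_w = 0.0
        tot_w = 0.0
        for b in BASES:
            if b == codon[j]:
                continue
            alt = codon[:j] + b + codon[j + 1:]
            w = R if (scheme == "weighted" and is_transition(codon[j], b)) else 1.0
            tot_w += w
            if alt not in STOP_CODONS and AA[alt] == AA[codon]:
                syn_w += w
        s += syn_w / tot_w
    return s, 3.0 - s


def ng_diff_counts(codon_a: str, codon_b: str):
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All k! orderings of the k differing positions are enumerated; orderings
    passing through a stop codon are discarded.  If every pathway is blocked
    by stops, the differences are counted as all nonsynonymous (fallback).
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c not in AA:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [j for j in range(3) if a[j] != b[j]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    syn_totals = []
    for order in itertools.permutations(diff_pos):
        cur = a
        syn = 0.0
        ok = True
        for j in order:
            nxt = cur[:j] + b[j] + cur[j + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AA[nxt] == AA[cur]:
                syn += 1.0
            cur = nxt
        if ok:
            syn_totals.append(syn)
    if not syn_totals:
        return 0.0, float(k)
    sd = float(np.mean(syn_totals))
    return sd, float(k) - sd


@lru_cache(maxsize=None)
def _site_array(scheme: str, R: float) -> np.ndarray:
    out = np.empty(N_SENSE)
    for i, c in enumerate(SENSE_CODONS):
        out[i] = ng_site_counts(c, scheme, R)[0]
    return out


@lru_cache(maxsize=None)
def _diff_arrays() -> tuple[np.ndarray, np.ndarray]:
    sd = np.zeros((N_SENSE, N_SENSE))
    nd = np.zeros((N_SENSE, N_SENSE))
    for i, a in enumerate(SENSE_CODONS):
        for j in range(i + 1, N_SENSE):
            s, n = ng_diff_counts(a, SENSE_CODONS[j])
            sd[i, j] = sd[j, i] = s
            nd[i, j] = nd[j, i] = n
    return sd, nd


def syn_sites_array(scheme: str = "unweighted", R: float = 2.0) -> np.ndarray:
    """Per-sense-codon synonymous site counts, indexed by CODON_INDEX."""
    return _site_array(scheme, float(R))


def diff_arrays() -> tuple[np.ndarray, np.ndarray]:
    """(Sd, Nd) 61x61 pathway-averaged difference-count matrices."""
    return _diff_arrays()


def codon_index_vector(codons) -> np.ndarray:
    """Map an iterable of codon strings to sense-codon indices (-1 if not sense)."""
    return np.array([CODON_INDEX.get(c, -1) for c in codons], dtype=np.int64)


def translate(codon: str) -> str:
    codon = codon.upper()
    if codon in STOP_CODONS:
        return "*"
    return AA[codon]
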