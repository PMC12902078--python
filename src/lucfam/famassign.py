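"""Gene-family assignment via diagnostic sites and mosaic (recombinant) detection.

A diagnostic site is an alignment column fixed within each of two families
but different between them.  Haplotypes are labelled by majority vote over
the diagnostic columns they cover; putative recombinants are detected by a
single-breakpoint minimum-discordance scan over the ordered diagnostic
sites.  Mosaic-flagged haplotypes are excluded from downstream diversity
and phylogenetic analyses by default because their segments have distinct
evolutionary histories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

_ACGT = frozenset("ACGT")


@dataclass
class DiagnosticSiteSet:
    family_a: str
    family_b: str
    sites: list[tuple[int, str, str]]   # (1-based column, allele in A, allele in B)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class MosaicCall:
    is_mosaic: bool
    breakpoint_interval: tuple[int, int] | None   # 1-based columns flanking the switch
    segment_labels: tuple[str, str] | None
    discordance_single: int | None
    discordance_two_segment: int | None
    evaluable: bool = True
    n_sites_covered: int = 0


def find_diagnostic_sites(fam_a_rows: list[str], fam_b_rows: list[str],
                          family_a: str = "A", family_b: str = "B") -> DiagnosticSiteSet:
    """Columns fixed-and-different between two aligned families (gaps skipped)."""
    for name, rows in ((family_a, fam_a_rows), (family_b, fam_b_rows)):
        if len(rows) < 2:
            warnings.warn(f"family {name} has < 2 sequences; "
                          "'fixed' means unanimous over what is present")
    L = min(len(r) for r in fam_a_rows + fam_b_rows)
    sites = []
    for c in range(L):
        a_alleles = {r[c] for r in fam_a_rows}
        b_alleles = {r[c] for r in fam_b_rows}
        if len(a_alleles) != 1 or len(b_alleles) != 1:
            continue
        a, b = next(iter(a_alleles)), next(iter(b_alleles))
        if a not in _ACGT or b not in _ACGT or a == b:
            continue
        sites.append((c + 1, a, b))
    return DiagnosticSiteSet(family_a=family_a, family_b=family_b, sites=sites)


def _site_votes(row: str, diag: DiagnosticSiteSet) -> list[tuple[int, str]]:
    """(column, vote) over covered diagnostic sites; vote in {A-label, B-label}."""
    votes = []
    for col, a, b in diag.sites:
        if col > len(row):
            continue
        ch = row[col - 1]
        if ch == a:
            votes.append((col, diag.family_a))
        elif ch == b:
            votes.append((col, diag.family_b))
    return votes


def assign_family(row: str, diag: DiagnosticSiteSet,
                  ambiguity_threshold: float = 0.8):
    """Majority-vote family label with per-site vote vector.

    Returns (label, score, votes).  Ties and scores below the ambiguity
    threshold give 'ambiguous' (a cue to run mosaic detection); a haplotype
    covering no informative column is 'unassigned'.
    """
    votes = _site_votes(row, diag)
    if not votes:
        return "unassigned", 0.0, votes
    n_a = sum(1 for _, v in votes if v == diag.family_a)
    n_b = len(votes) - n_a
    if n_a == n_b:
        return "ambiguous", 0.5, votes
    label, score = ((diag.family_a, n_a / len(votes)) if n_a > n_b
                    else (diag.family_b, n_b / len(votes)))
    if score < ambiguity_threshold:
        return "ambiguous", score, votes
    return label, score, votes


def detect_mosaic(row: str, diag: DiagnosticSiteSet, min_gain: int = 3) -> MosaicCall:
    """Single-breakpoint minimum-discordance scan over diagnostic sites.

    The haplotype is mosaic when the best two-segment labelling saves at
    least ``min_gain`` discordant sites over the best single label.
    """
    votes = _site_votes(row, diag)
    k = len(votes)
    if k < 4:
        return MosaicCall(is_mosaic=False, breakpoint_interval=None,
                          segment_labels=None, discordance_single=None,
                          discordance_two_segment=None, evaluable=False,
                          n_sites_covered=k)
    labels = (diag.family_a, diag.family_b)
    v = [lb for _, lb in votes]
    cols = [col for col, _ in votes]

    def mismatches(segment, lb):
        return sum(1 for x in segment if x != lb)

    single = min(mismatches(v, lb) for lb in labels)
    best = None
    for b in range(1, k):           # breakpoint between votes b-1 and b
        for la in labels:
            for lb2 in labels:      # equal labels allowed: degenerates to single
                d = mismatches(v[:b], la) + mismatches(v[b:], lb2)
                cand = (d, b, (la, lb2))
                if best is None or cand[0] < best[0]:
                    best = cand
    d2, b, seg = best
    gain = single - d2
    return MosaicCall(
        is_mosaic=gain >= min_gain,
        breakpoint_interval=(cols[b - 1], cols[b]),
        segment_labels=seg,
        discordance_single=single,
        discordance_two_segment=d2,
        evaluable=True,
        n_sites_covered=k,
    )


def find_exclusive_shared_variants(group_rows: list[str],
                                   background_rows: list[str]) -> list[int]:
    """Columns (1-based) where the group is unanimous for an allele absent
    from every background sequence."""
    if not group_rows or not background_rows:
        raise ValueError("group and background must be non-empty")
    L = min(len(r) for r in group_rows + background_rows)
    out = []
    for c in range(L):
        g = {r[c] for r in group_rows}
        if len(g) != 1:
            continue
        allele = next(iter(g))
        if allele not in _ACGT:
            continue
        if all(r[c] != allele for r in background_rows):
            out.append(c + 1)
    return out
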