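"""Exon/intron projection onto haplotypes and alternative splice-motif search.

When an intron's boundaries cannot be fixed from mRNA evidence, all GT
donor and AG acceptor dinucleotides near the expected positions are
enumerated, and each donor x acceptor combination is checked for reading-
frame preservation (spliced length change divisible by 3) and absence of
premature stop codons in the spliced CDS.  The module only enumerates
candidate combinations; it never selects one.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _codon
from .core import AnchoredAlignment, ReferenceAnnotation, SeqRecord


@dataclass
class ProjectedInterval:
    kind: str                       # "exon" or "intron"
    index: int                      # 1-based exon/intron number
    start: int | None               # 1-based on the haplotype; None if empty
    end: int | None
    empty: bool = False
    gt_ok: bool | None = None       # introns: GT at 5' end
    ag_ok: bool | None = None       # introns: AG at 3' end


@dataclass
class SpliceCandidate:
    donor_position: int             # 1-based start of the GT
    acceptor_position: int          # 1-based start of the AG
    frame_preserving: bool
    premature_stop: bool

    @property
    def valid(self) -> bool:
        return self.frame_preserving and not self.premature_stop


def _hap_coordinates(member_row: str) -> list[int | None]:
    """Per-column 1-based haplotype coordinate (None where the member is gapped)."""
    out = []
    pos = 0
    for ch in member_row:
        if ch == "-":
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def project_annotation(member_index: int, annot: ReferenceAnnotation,
                       aln: AnchoredAlignment) -> list[ProjectedInterval]:
    """Map reference exon/intron boundaries through the alignment onto one member.

    Boundaries falling inside a deletion snap to the nearest retained
    haplotype position toward the interval's interior; fully deleted
    intervals are reported empty.  Intron GT/AG presence is verified.
    """
    row = aln.members[member_index].nucleotides
    coords = _hap_coordinates(row)
    hap = row.replace("-", "")

    ref_to_col = {int(aln.column_ref[c]): c for c in range(aln.n_columns)
                  if aln.column_ref[c] > 0}

    def project(start_ref: int, end_ref: int) -> tuple[int | None, int | None]:
        start = end = None
        for p in range(start_ref, end_ref + 1):          # snap start inward
            c = ref_to_col.get(p)
            if c is not None and coords[c] is not None:
                start = coords[c]
                break
        for p in range(end_ref, start_ref - 1, -1):      # snap end inward
            c = ref_to_col.get(p)
            if c is not None and coords[c] is not None:
                end = coords[c]
                break
        return start, end

    out: list[ProjectedInterval] = []
    exons = annot.exon_intervals
    for i, (s, e) in enumerate(exons):
        hs, he = project(s, e)
        out.append(ProjectedInterval(kind="exon", index=i + 1, start=hs, end=he,
                                     empty=hs is None))
        if i < len(exons) - 1:
            is_, ie = exons[i][1] + 1, exons[i + 1][0] - 1
            hs2, he2 = project(is_, ie)
            iv = ProjectedInterval(kind="intron", index=i + 1, start=hs2, end=he2,
                                   empty=hs2 is None)
            if hs2 is not None and he2 is not None and he2 > hs2:
                iv.gt_ok = hap[hs2 - 1:hs2 + 1] == "GT"
                iv.ag_ok = hap[he2 - 2:he2] == "AG"
            out.append(iv)
    return out


def enumerate_splice_candidates(seq: str, expected_donor: int,
                                expected_acceptor: int, window: int = 60,
                                cds_start: int = 1):
    """All GT/AG motif pairs near the expected intron boundaries.

    ``expected_donor``/``expected_acceptor`` are the 1-based starts of the
    annotated GT and AG dinucleotides.  Frame preservation requires the
    candidate intron length to differ from the reference intron length by a
    multiple of 3; the premature-stop check translates the spliced CDS from
    ``cds_start``.  Returns (candidates, n_valid).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not (1 <= expected_donor < expected_acceptor <= len(seq) - 1):
        raise ValueError("expected positions outside the sequence")
    seq = seq.upper()

    def motif_positions(motif: str, center: int) -> list[int]:
        lo = max(1, center - window)
        hi = min(len(seq) - 1, center + window)
        return [p for p in range(lo, hi + 1) if seq[p - 1:p + 1] == motif]

    donors = motif_positions("GT", expected_donor)
    acceptors = motif_positions("AG", expected_acceptor)
    ref_intron_len = expected_acceptor + 2 - expected_donor

    candidates: list[SpliceCandidate] = []
    n_valid = 0
    for d in donors:
        for a in acceptors:
            if d >= a:
                continue
            intron_len = a + 2 - d
            frame_ok = (intron_len - ref_intron_len) % 3 == 0
            spliced = seq[:d - 1] + seq[a + 1:]
            cds = spliced[cds_start - 1:]
            stop = False
            n_codons = len(cds) // 3
            for ci in range(n_codons - 1):    # internal codons only
                codon = cds[3 * ci:3 * ci + 3]
                if codon in _codon.STOP_CODONS:
                    stop = True
                    break
            cand = SpliceCandidate(donor_position=d, acceptor_position=a,
                                   frame_preserving=frame_ok, premature_stop=stop)
            candidates.append(cand)
            if cand.valid:
                n_valid += 1
    return candidates, n_valid
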