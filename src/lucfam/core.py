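"""Domain types, reference-anchored alignment and site-class masking.

Coordinates are 1-based inclusive throughout (GenBank feature convention);
alignment columns are 1-based as well.  Sequences are plus-strand: read
orientation is normalized at intake in :mod:`lucfam.hapcall`, not here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align

from . import _codon

GAP = "-"
_DNA_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                                "TGCAYRMKVHDBNtgcayrmkvhdbn")


def revcomp(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A sequence with provenance: a clone, a read, a reference or a simulated truth."""

    id: str
    nucleotides: str
    sample_id: str = ""
    qualities: list[int] | None = None
    evidence_source: str = "SIM"  # one of PCS, MPS, REF, SIM

    def __post_init__(self):
        if not self.nucleotides:
            raise ValueError(f"{self.id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.nucleotides):
            raise ValueError(f"{self.id}: qualities/sequence length mismatch")
        if self.evidence_source not in ("PCS", "MPS", "REF", "SIM"):
            raise ValueError(f"{self.id}: bad evidence_source {self.evidence_source!r}")

    def ungapped(self) -> str:
        return self.nucleotides.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class ReferenceAnnotation:
    """Exon layout of a locus reference plus an optional analysed-segment restriction."""

    locus: str
    reference_id: str
    exon_intervals: list[tuple[int, int]]
    analysed_segment: tuple[int, int] | None = None
    exclusion_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        ivs = [tuple(iv) for iv in self.exon_intervals]
        if not ivs:
            raise ValueError(f"{self.locus}: no exons")
        for s, e in ivs:
            if s < 1 or e < s:
                raise ValueError(f"{self.locus}: bad exon interval [{s},{e}]")
        ivs.sort()
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.locus}: overlapping exons [{s1},{e1}],[{s2},{e2}]")
        self.exon_intervals = ivs
        if sum(e - s + 1 for s, e in ivs) < 3:
            raise ValueError(f"{self.locus}: concatenated exon length < 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exon_intervals)

    def intron_intervals(self, ref_length: int | None = None) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exon_intervals, self.exon_intervals[1:]):
            out.append((e1 + 1, s2 - 1))
        return out


@dataclass
class AnchoredAlignment:
    """Member sequences merged on the coordinates of a single reference.

    ``column_ref[c]`` gives the 1-based reference position of column ``c``
    (0-based internally), or 0 for columns that are insertions relative to
    the reference.  Ungapping any member row recovers its input exactly.
    """

    reference: SeqRecord          # gapped reference row
    members: list[SeqRecord]      # gapped member rows, all equal length
    column_ref: np.ndarray        # int array, len == n_columns; 0 => insertion column
    excluded_columns: frozenset[int] = frozenset()   # 0-based column indices
    unalignable: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.column_ref)

    @property
    def insertion_columns(self) -> list[int]:
        return [c for c in range(self.n_columns) if self.column_ref[c] == 0]

    def columns_for_ref(self, start: int, end: int) -> list[int]:
        """Alignment columns mapping to reference positions start..end (1-based)."""
        return [c for c in range(self.n_columns) if start <= self.column_ref[c] <= end]

    def ref_position_of(self, column: int) -> int:
        """1-based reference position of a 0-based column (0 for insertions)."""
        return int(self.column_ref[column])

    def rows(self) -> list[str]:
        return [m.nucleotides for m in self.members]


@dataclass
class SiteClassMask:
    """Per-column site classification and the codon frame of the coding part.

    ``col_class`` assigns each alignment column one of CODING/NONCODING/
    EXCLUDED.  ``codon_columns`` lists, per retained codon, its three
    0-based alignment columns; codons touching any excluded column are
    dropped whole so that the synonymous + nonsynonymous site decomposition
    stays exactly conservative (s + n == 3 per codon).
    """

    CODING, NONCODING, EXCLUDED = 0, 1, 2

    col_class: np.ndarray
    codon_columns: list[tuple[int, int, int]]
    noncoding_columns: np.ndarray

    def codon_strings(self, row: str) -> list[str]:
        return ["".join(row[c] for c in cols) for cols in self.codon_columns]

    def syn_site_fractions(self, codon: str, scheme: str = "unweighted", R: float = 2.0):
        return _codon.ng_site_counts(codon, scheme, R)


def _make_aligner(match=2.0, mismatch=-3.0, gap_open=-8.0, gap_extend=-1.0,
                  free_end_gaps=True) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if free_end_gaps:
        # members covering only part of the reference (amplicon reads,
        # truncated clones) should not pay for terminal gaps
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _pairwise_to_ref(aln) -> tuple[dict[int, str], dict[int, str], float]:
    """Decompose one Biopython pairwise alignment (ref=target, seq=query).

    Returns (base at each covered reference position or '-' if deleted,
    insertion strings keyed by the reference position they follow,
    fractional identity over the aligned span).
    """
    ref_aln, seq_aln = str(aln[0]), str(aln[1])
    per_pos: dict[int, str] = {}
    insertions: dict[int, str] = {}
    rpos = 0
    matches = 0
    span = 0
    for rb, sb in zip(ref_aln, seq_aln):
        if rb != GAP:
            rpos += 1
            per_pos[rpos] = sb
            if sb != GAP:
                span += 1
                if rb.upper() == sb.upper():
                    matches += 1
        else:
            if sb != GAP:
                insertions[rpos] = insertions.get(rpos, "") + sb
    # trim terminal end-gaps: positions outside the member's span are absence,
    # not deletions; they stay '-' either way, so nothing to do.
    identity = matches / span if span else 0.0
    return per_pos, insertions, identity


def anchor_align(seqs: list[SeqRecord], ref: SeqRecord,
                 match: float = 2.0, mismatch: float = -3.0,
                 gap_open: float = -8.0, gap_extend: float = -1.0,
                 min_identity: float = 0.5,
                 free_end_gaps: bool = True) -> AnchoredAlignment:
    """Globally align each member to the reference and merge on its coordinates.

    Insertion columns (absent from the reference) are appended after the
    reference position they follow; multiple members inserting at the same
    position share a left-justified insertion block.  Members below
    ``min_identity`` over their aligned span are flagged unalignable and
    excluded with a warning.  ``free_end_gaps`` suits partial-coverage
    members (reads); disable it when aligning full-length, highly diverged
    haplotypes, where free ends would silently trim low-identity flanks.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if GAP in ref.nucleotides:
        raise ValueError("reference must be ungapped")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend,
                            free_end_gaps=free_end_gaps)
    L = len(ref.nucleotides)

    decomposed = []
    unalignable = []
    for rec in seqs:
        aln = aligner.align(ref.nucleotides, rec.ungapped())[0]
        per_pos, ins, ident = _pairwise_to_ref(aln)
        if ident < min_identity:
            warnings.warn(f"{rec.id}: identity {ident:.2f} < {min_identity:.2f}, "
                          "flagged unalignable and excluded")
            unalignable.append(rec.id)
            continue
        decomposed.append((rec, per_pos, ins))

    ins_len = {p: 0 for p in range(L + 1)}
    for _, _, ins in decomposed:
        for p, s in ins.items():
            ins_len[p] = max(ins_len[p], len(s))

    column_ref: list[int] = []
    for p in range(0, L + 1):
        if p >= 1:
            column_ref.append(p)
        column_ref.extend([0] * ins_len[p])
    column_ref_arr = np.array(column_ref, dtype=np.int64)

    def build_row(per_pos: dict[int, str], ins: dict[int, str], ref_row: bool = False) -> str:
        out = []
        for p in range(0, L + 1):
            if p >= 1:
                if ref_row:
                    out.append(ref.nucleotides[p - 1])
                else:
                    out.append(per_pos.get(p, GAP))
            block = ins.get(p, "") if not ref_row else ""
            out.append(block + GAP * (ins_len[p] - len(block)))
        return "".join(out)

    ref_row = SeqRecord(id=ref.id, sample_id=ref.sample_id,
                        nucleotides=build_row({}, {}, ref_row=True),
                        evidence_source="REF")
    members = [
        replace(rec, nucleotides=build_row(per_pos, ins), qualities=None)
        for rec, per_pos, ins in decomposed
    ]
    return AnchoredAlignment(reference=ref_row, members=members,
                             column_ref=column_ref_arr, unalignable=unalignable)


def trim_primer_regions(aln: AnchoredAlignment,
                        primer_spans: list[tuple[int, int]]) -> AnchoredAlignment:
    """Mark columns covering primer spans (reference intervals) as excluded."""
    ref_len = int(aln.column_ref.max(initial=0))
    excluded = set(aln.excluded_columns)
    for s, e in primer_spans:
        if s < 1 or e > ref_len or e < s:
            raise ValueError(f"primer span [{s},{e}] outside reference 1..{ref_len}")
        excluded.update(c for c in range(aln.n_columns) if s <= aln.column_ref[c] <= e)
    return replace(aln, excluded_columns=frozenset(excluded))


def build_site_mask(aln: AnchoredAlignment, annot: ReferenceAnnotation) -> SiteClassMask:
    """Classify alignment columns as coding/noncoding/excluded and frame the codons.

    Exon columns become coding, intron columns noncoding.  Columns outside
    the analysed segment, inside listed exclusion intervals or primer spans,
    and insertion columns are excluded; codons touching an excluded column
    are dropped whole.
    """
    if annot.cds_length % 3 != 0:
        raise ValueError(
            f"{annot.locus}: exon intervals {annot.exon_intervals} concatenate to "
            f"{annot.cds_length} nt, not a whole number of codons")
    n = aln.n_columns
    cls = np.full(n, SiteClassMask.EXCLUDED, dtype=np.int8)
    in_exon = np.zeros(n, dtype=bool)
    for s, e in annot.exon_intervals:
        for c in aln.columns_for_ref(s, e):
            in_exon[c] = True
    for c in range(n):
        p = int(aln.column_ref[c])
        if p == 0:
            continue  # insertion column: excluded
        cls[c] = SiteClassMask.CODING if in_exon[c] else SiteClassMask.NONCODING

    def exclude_interval(s, e):
        for c in aln.columns_for_ref(s, e):
            cls[c] = SiteClassMask.EXCLUDED

    if annot.analysed_segment is not None:
        lo, hi = annot.analysed_segment
        for c in range(n):
            p = int(aln.column_ref[c])
            if p and not (lo <= p <= hi):
                cls[c] = SiteClassMask.EXCLUDED
    for s, e in annot.exclusion_intervals:
        exclude_interval(s, e)
    for c in aln.excluded_columns:
        cls[c] = SiteClassMask.EXCLUDED

    # codon framing over the concatenated exons, in reference coordinates
    ref_to_col = {int(aln.column_ref[c]): c for c in range(n) if aln.column_ref[c] > 0}
    cds_cols: list[int] = []
    for s, e in annot.exon_intervals:
        for p in range(s, e + 1):
            cds_cols.append(ref_to_col.get(p, -1))
    codon_columns = []
    for i in range(0, len(cds_cols) - 2, 3):
        triple = cds_cols[i:i + 3]
        if any(c < 0 for c in triple):
            continue
        if any(cls[c] == SiteClassMask.EXCLUDED for c in triple):
            continue
        codon_columns.append(tuple(triple))
    noncoding = np.array(
        [c for c in range(n) if cls[c] == SiteClassMask.NONCODING], dtype=np.int64)
    return SiteClassMask(col_class=cls, codon_columns=codon_columns,
                         noncoding_columns=noncoding)
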