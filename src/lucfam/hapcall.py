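"""Amplicon haplotype calling with a cross-evidence validation cascade.

Candidate calling is an abundance-parent Poisson error model: reads are
orientation-normalized, dereplicated, and processed in decreasing
abundance.  A candidate observed n_c times whose nearest more-abundant
accepted parent (n_p reads) lies k edits away has an expected
error-derived count

    lambda = n_p * (eps/3)^k * (1 - eps)^(L - k)

and posterior score P(N < n_c | N ~ Poisson(lambda)); candidates scoring
<= 0.95 are merged into their parent (counts added).  A singleton with any
more-abundant accepted parent is always absorbed into its nearest parent:
with one observation the error hypothesis can never be rejected (the
limiting behaviour of the conditioned abundance p-value used by amplicon
denoisers), which is what lets the caller soak up the cloud of unique
error reads around each true haplotype.  The most abundant candidate per
sample is always accepted.

The validation cascade then applies, in order: the posterior threshold
(> 0.95), rejection of 1-2 nt indels unless an identical indel (position,
length, bases) occurs in a cloned sequence, rejection of premature stop
codons unless present in a clone, and a per-sample 15% read-frequency
floor waived for haplotypes matching a clone over the sequenced segment or
observed in two or more samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy import stats

from . import _codon
from .core import ReferenceAnnotation, SeqRecord, revcomp

GAP_CHAR = "-"
POSTERIOR_THRESHOLD = 0.95
MIN_FREQ = 0.15
MIN_READ_LENGTH = 151      # "longer than 150 bp"


@dataclass
class Haplotype:
    sequence: str
    locus: str = ""
    read_counts: dict[str, int] = field(default_factory=dict)
    clone_count: int = 0
    samples_observed: set[str] = field(default_factory=set)
    posterior_score: float = 1.0
    flags: set[str] = field(default_factory=set)
    family: str | None = None

    @property
    def total_reads(self) -> int:
        return sum(self.read_counts.values())


@dataclass
class RegistryEntry:
    sequence: str
    names: list[str]
    sources: set[str]
    clone_count: int
    read_counts: dict[str, int]
    samples_observed: set[str]


@dataclass
class EvidenceRegistry:
    """Per-locus union of PCS and accepted MPS haplotypes, matched on the
    sequenced (MPS) segment."""
    locus: str
    entries: list[RegistryEntry] = field(default_factory=list)


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# read intake

def filter_reads(reads: list[SeqRecord], min_len: int = MIN_READ_LENGTH):
    """Keep reads of length >= min_len; returns (kept, stats)."""
    import warnings
    kept = [r for r in reads if len(r.nucleotides) >= min_len]
    stats_ = {"input": len(reads), "kept": len(kept),
              "discarded": len(reads) - len(kept)}
    if not kept:
        warnings.warn("no reads passed the length filter")
    return kept, stats_


def orient_reads(reads: list[SeqRecord], ref: SeqRecord) -> list[SeqRecord]:
    """Reverse-complement reads that align better to the reference reversed."""
    from dataclasses import replace
    out = []
    for r in reads:
        fwd = edit_distance(r.nucleotides, ref.nucleotides)
        rc = revcomp(r.nucleotides)
        rev = edit_distance(rc, ref.nucleotides)
        if rev < fwd:
            out.append(replace(r, nucleotides=rc,
                               qualities=list(reversed(r.qualities))
                               if r.qualities else None))
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# candidate calling

def error_posterior(n_parent: int, n_cand: int, k: int, L: int,
                    eps: float) -> tuple[float, float]:
    """(lambda, posterior) of the abundance-parent Poisson error model.

    lambda = n_parent (eps/3)^k (1-eps)^(L-k) is the expected count of reads
    from the parent carrying exactly this candidate's k errors; the
    posterior is P(N < n_cand | N ~ Poisson(lambda)).
    """
    lam = n_parent * (eps / 3.0) ** k * (1.0 - eps) ** (L - k)
    return lam, float(stats.poisson.cdf(n_cand - 1, lam))


def call_candidates(reads: list[SeqRecord], ref: SeqRecord,
                    eps: float, sample_id: str | None = None,
                    posterior_threshold: float = POSTERIOR_THRESHOLD) -> list[Haplotype]:
    """Dereplicate one sample's oriented reads into accepted candidates."""
    if not 0.0 < eps < 1.0:
        raise ValueError("error rate eps must be in (0, 1)")
    if not reads:
        return []
    sample = sample_id or reads[0].sample_id or "sample"
    counts: dict[str, int] = {}
    for r in reads:
        counts[r.nucleotides] = counts.get(r.nucleotides, 0) + 1
    order = sorted(counts, key=lambda s: (-counts[s], s))

    accepted: list[dict] = []
    for seq in order:
        n_c = counts[seq]
        if not accepted:
            accepted.append({"seq": seq, "count": n_c, "posterior": 1.0})
            continue
        dists = [edit_distance(seq, a["seq"]) for a in accepted]
        pi = int(np.argmin(dists))
        k = dists[pi]
        parent = accepted[pi]
        lam, posterior = error_posterior(parent["count"], n_c, k, len(seq), eps)
        if n_c == 1 or posterior <= posterior_threshold:
            parent["count"] += n_c
        else:
            accepted.append({"seq": seq, "count": n_c, "posterior": posterior})
    return [
        Haplotype(sequence=a["seq"], locus=ref.id,
                  read_counts={sample: a["count"]},
                  samples_observed={sample}, posterior_score=a["posterior"])
        for a in accepted
    ]


def call_samples(reads_by_sample: dict[str, list[SeqRecord]], ref: SeqRecord,
                 eps: float, min_len: int = MIN_READ_LENGTH,
                 posterior_threshold: float = POSTERIOR_THRESHOLD) -> list[Haplotype]:
    """Length-filter, orient and call every sample, merging identical
    candidate sequences across samples."""
    merged: dict[str, Haplotype] = {}
    for sid in sorted(reads_by_sample):
        kept, _ = filter_reads(reads_by_sample[sid], min_len)
        if not kept:
            continue
        oriented = orient_reads(kept, ref)
        for h in call_candidates(oriented, ref, eps, sample_id=sid,
                                 posterior_threshold=posterior_threshold):
            if h.sequence in merged:
                m = merged[h.sequence]
                m.read_counts.update(h.read_counts)
                m.samples_observed |= h.samples_observed
                m.posterior_score = max(m.posterior_score, h.posterior_score)
            else:
                merged[h.sequence] = h
    out = list(merged.values())
    for h in out:
        if len(h.samples_observed) >= 2:
            h.flags.add("MULTI_SAMPLE")
    return sorted(out, key=lambda h: (-h.total_reads, h.sequence))


# ---------------------------------------------------------------------------
# indel / stop signatures

def _aligned_rows(query: str, target: str) -> tuple[str, str]:
    """Affine-gap global alignment rows (target_row, query_row).

    An affine aligner is used rather than a unit-cost edit path so that
    adjacent substitutions are never represented as paired indels.
    """
    from .core import _make_aligner
    aln = _make_aligner().align(target, query)[0]
    return str(aln[0]), str(aln[1])


def _cigar_walk(query: str, target: str):
    """Yield (op, length, target_pos, query_bases), target_pos being the
    1-based target position at (D) or after (I) which the op applies.
    Terminal gaps (partial coverage) are not reported."""
    t_row, q_row = _aligned_rows(query, target)
    events = []
    qpos = tpos = 0
    i = 0
    n = len(t_row)
    while i < n:
        if t_row[i] == GAP_CHAR:          # insertion run in query
            j = i
            bases = []
            while j < n and t_row[j] == GAP_CHAR:
                bases.append(q_row[j])
                j += 1
            events.append(("I", j - i, tpos, "".join(bases), qpos))
            qpos += j - i
            i = j
        elif q_row[i] == GAP_CHAR:        # deletion run in query
            j = i
            while j < n and j < len(q_row) and q_row[j] == GAP_CHAR and t_row[j] != GAP_CHAR:
                j += 1
            events.append(("D", j - i, tpos + 1, "", qpos))
            tpos += j - i
            i = j
        else:
            qpos += 1
            tpos += 1
            i += 1
    # drop terminal events (end gaps from partial coverage)
    for op, ln, pos, bases, qp in events:
        if (op == "I" and (qp == 0 or qp + ln == len(query))) or \
           (op == "D" and (qp == 0 or qp == len(query))):
            continue
        yield (op, ln, pos, bases)


def indel_signature(seq: str, ref: str, max_len: int = 2) -> set[tuple]:
    """Short-indel signature (op, ref position, length, inserted bases)."""
    return {(op, pos, ln, bases) for op, ln, pos, bases in _cigar_walk(seq, ref)
            if ln <= max_len}


def long_indels(seq: str, ref: str, min_len: int = 3) -> set[tuple]:
    return {(op, pos, ln, bases) for op, ln, pos, bases in _cigar_walk(seq, ref)
            if ln >= min_len}


def _seq_on_ref(seq: str, ref: str) -> dict[int, str]:
    """Map 1-based reference positions to the bases ``seq`` carries there."""
    t_row, q_row = _aligned_rows(seq, ref)
    out: dict[int, str] = {}
    tpos = 0
    for tb, qb in zip(t_row, q_row):
        if tb != GAP_CHAR:
            tpos += 1
            if qb != GAP_CHAR:
                out[tpos] = qb
    return out


def stop_codon_indices(seq: str, ref: str, annot: ReferenceAnnotation) -> set[int]:
    """Indices (0-based, excluding the final codon) of premature stops in the
    CDS that ``seq`` projects onto the reference exon layout."""
    on_ref = _seq_on_ref(seq, ref)
    cds_positions = [p for s, e in annot.exon_intervals for p in range(s, e + 1)]
    n_codons = len(cds_positions) // 3
    stops = set()
    for ci in range(n_codons):
        triple = cds_positions[3 * ci:3 * ci + 3]
        bases = [on_ref.get(p) for p in triple]
        if any(b is None for b in bases):
            continue
        codon = "".join(bases)
        if codon in _codon.STOP_CODONS and ci < n_codons - 1:
            stops.add(ci)
    return stops


def clone_segment(clone: SeqRecord, ref: SeqRecord) -> str:
    """The clone's stretch matching the sequenced (amplicon) reference,
    located by infix alignment of the reference within the clone."""
    res = edlib.align(ref.nucleotides, clone.nucleotides, mode="HW", task="locations")
    start, end = res["locations"][0]
    return clone.nucleotides[start:end + 1]


# ---------------------------------------------------------------------------
# validation cascade

@dataclass
class CascadeAudit:
    sequence: str
    stage: str
    detail: str


def apply_validation_cascade(cands: list[Haplotype], clones: list[SeqRecord],
                             ref: SeqRecord,
                             annot: ReferenceAnnotation | None = None,
                             posterior: float = POSTERIOR_THRESHOLD,
                             min_freq: float = MIN_FREQ):
    """Sequential filtering with clone (PCS) and cross-sample exceptions.

    Returns (accepted, audit log).  Without clones the indel/stop
    exceptions are unavailable (the rules still fire); a sample whose
    surviving read total is zero at the frequency stage is an error.
    """
    audit: list[CascadeAudit] = []
    clone_segments = [clone_segment(c, ref) for c in clones]
    clone_indels = set()
    clone_stops: set[int] = set()
    for cs in clone_segments:
        clone_indels |= indel_signature(cs, ref.nucleotides)
        if annot is not None:
            clone_stops |= stop_codon_indices(cs, ref.nucleotides, annot)

    alive = []
    for h in cands:
        if h.posterior_score <= posterior:
            audit.append(CascadeAudit(h.sequence, "posterior",
                                      f"posterior {h.posterior_score:.4f} <= {posterior}"))
            continue
        alive.append(h)

    survivors = []
    for h in alive:
        sig = indel_signature(h.sequence, ref.nucleotides)
        unsupported = sig - clone_indels
        if unsupported:
            audit.append(CascadeAudit(h.sequence, "indel",
                                      f"1-2 nt indel(s) {sorted(unsupported)} not in clones"))
            continue
        if sig:
            h.flags.add("HAS_SHORT_INDEL")
            h.flags.add("PCS_MATCHED_INDEL")
        survivors.append(h)
    alive = survivors

    if annot is not None:
        survivors = []
        for h in alive:
            stops = stop_codon_indices(h.sequence, ref.nucleotides, annot)
            unsupported = stops - clone_stops
            if unsupported:
                audit.append(CascadeAudit(h.sequence, "stop",
                                          f"premature stop at codon(s) {sorted(unsupported)}"
                                          " not in clones"))
                continue
            if stops:
                h.flags.add("HAS_PREMATURE_STOP")
            survivors.append(h)
        alive = survivors

    # per-sample frequencies over the reads of still-alive candidates
    totals: dict[str, int] = {}
    for h in alive:
        for sid, n in h.read_counts.items():
            totals[sid] = totals.get(sid, 0) + n
    for sid, tot in totals.items():
        if tot == 0:
            raise ValueError(f"sample {sid}: zero surviving reads, frequencies undefined")

    accepted = []
    for h in alive:
        pcs = any(h.sequence == cs for cs in clone_segments)
        if pcs:
            h.flags.add("PCS_MATCHED")
            h.clone_count = sum(1 for cs in clone_segments if cs == h.sequence)
        freqs = {sid: n / totals[sid] for sid, n in h.read_counts.items() if sid in totals}
        max_freq = max(freqs.values()) if freqs else 0.0
        if max_freq >= min_freq:
            accepted.append(h)
        elif pcs:
            accepted.append(h)
        elif len(h.samples_observed) >= 2:
            h.flags.add("MULTI_SAMPLE")
            accepted.append(h)
        else:
            h.flags.add("WEAKLY_SUPPORTED")
            audit.append(CascadeAudit(h.sequence, "frequency",
                                      f"max frequency {max_freq:.3f} < {min_freq}, "
                                      "no PCS match, single sample"))
    return accepted, audit


def build_registry(accepted: list[Haplotype], clones: list[SeqRecord],
                   ref: SeqRecord, locus: str = "") -> EvidenceRegistry:
    """Union PCS haplotypes with accepted MPS haplotypes, matching identity
    over the sequenced segment."""
    reg = EvidenceRegistry(locus=locus or ref.id)
    seg_counts: dict[str, list[str]] = {}
    for c in clones:
        seg = clone_segment(c, ref)
        seg_counts.setdefault(seg, []).append(c.id)
    seen: dict[str, RegistryEntry] = {}
    for h in accepted:
        ids = seg_counts.get(h.sequence, [])
        e = RegistryEntry(sequence=h.sequence, names=[f"MPS:{h.sequence[:12]}"] + ids,
                          sources={"MPS"} | ({"PCS"} if ids else set()),
                          clone_count=len(ids), read_counts=dict(h.read_counts),
                          samples_observed=set(h.samples_observed))
        seen[h.sequence] = e
    for seg, ids in seg_counts.items():
        if seg not in seen:
            seen[seg] = RegistryEntry(sequence=seg, names=ids, sources={"PCS"},
                                      clone_count=len(ids), read_counts={},
                                      samples_observed={i.split(":")[0] for i in ids})
    reg.entries = list(seen.values())
    return reg


# ---------------------------------------------------------------------------
# supporting-evidence statistics

@dataclass
class MutationProfileResult:
    weak_mean: float | None
    weak_se: float | None
    strong_mean: float | None
    strong_se: float | None
    t_stat: float | None
    p_value: float | None
    verdict: str
    n_weak: int = 0
    n_strong: int = 0


def mutation_profile_statistic(accepted: list[Haplotype]) -> MutationProfileResult:
    """Compare nearest-neighbour mutation distances of weakly supported
    haplotypes against the strongly supported set (Welch two-sided).

    Strong: detected in >= 2 independent samples or by both PCS and MPS.
    """
    strong = [h for h in accepted
              if len(h.samples_observed) >= 2 or "PCS_MATCHED" in h.flags]
    weak = [h for h in accepted if h not in strong]
    if len(strong) < 2:
        return MutationProfileResult(None, None, None, None, None, None,
                                     verdict="undefined: strong set < 2",
                                     n_weak=len(weak), n_strong=len(strong))

    def nearest(h, pool):
        return min(edit_distance(h.sequence, o.sequence) for o in pool if o is not h)

    strong_d = np.array([nearest(h, strong) for h in strong], dtype=float)
    s_mean = float(strong_d.mean())
    s_se = float(strong_d.std(ddof=1) / np.sqrt(len(strong_d))) if len(strong_d) > 1 else None
    if not weak:
        return MutationProfileResult(None, None, s_mean, s_se, None, None,
                                     verdict="no weak haplotypes",
                                     n_weak=0, n_strong=len(strong))
    weak_d = np.array([min(edit_distance(h.sequence, s.sequence) for s in strong)
                       for h in weak], dtype=float)
    w_mean = float(weak_d.mean())
    w_se = float(weak_d.std(ddof=1) / np.sqrt(len(weak_d))) if len(weak_d) > 1 else None
    if len(weak_d) > 1 and len(strong_d) > 1:
        t, p = stats.ttest_ind(weak_d, strong_d, equal_var=False)
        t, p = float(t), float(p)
    else:
        t = p = None
    verdict = ("profiles indistinguishable" if (p is None or p > 0.05)
               else "weak haplotypes differ from strong")
    return MutationProfileResult(w_mean, w_se, s_mean, s_se, t, p, verdict,
                                 n_weak=len(weak), n_strong=len(strong))


def correlate_clone_read_support(registry: EvidenceRegistry) -> float | None:
    """R^2 of ordinary least squares of clone count on total read count over
    haplotypes carrying both kinds of evidence; None below 3 points."""
    pts = [(sum(e.read_counts.values()), e.clone_count)
           for e in registry.entries
           if e.clone_count > 0 and sum(e.read_counts.values()) > 0]
    if len(pts) < 3:
        return None
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return 0.0
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2)
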