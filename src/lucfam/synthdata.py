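"""Ground-truthed simulator for multi-family, multi-copy luciferase-like loci.

Emulates the observed regime of a tandem luciferase gene family: a few
paralogous families whose founders are separated by substantial synonymous
divergence (Ks up to ~0.8), copies within a family at silent diversity in
the 0.13-0.16 range, strong purifying selection on amino-acid changes
(omega ~ 0.05), occasional recombinant alleles joining two families,
error-free Sanger-style clone sampling, and amplicon reads carrying
substitution errors plus strand-biased 1-2 nt indel errors.

Evolution is codon-level: synonymous changes are accepted at rate 1,
nonsynonymous at rate omega, changes creating stop codons are rejected,
and introns evolve neutrally at the same per-site depth as synonymous
sites.  Divergence targeting is iterative: mutations are applied in
batches until the realized Jukes-Cantor-corrected Ks (measured with the
same counting used by the statistics module) is within 5% of target.

Randomness: a single master seed; each (sample, stage) derives its own
stream by hashing, so adding a sample leaves the others' outputs
untouched, and a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from . import _codon
from .core import ReferenceAnnotation, SeqRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _substream(seed: int, name: str, stage: int) -> np.random.Generator:
    h = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, h, stage])


# ---------------------------------------------------------------------------
# configuration

@dataclass
class FamilyConfig:
    name: str
    n_copies: int = 3
    target_ks_within: float = 0.15
    target_ks_between: float = 0.0   # Ks from the parent family's founder
    parent: str | None = None        # None => founded at the ancestral root
    omega: float = 0.05


@dataclass
class ReadSimConfig:
    depth_mean: float = 1000.0
    sub_rate: float = 0.01
    indel_rate: float = 0.0
    indel_len_probs: tuple[float, float] = (0.8, 0.2)   # lengths 1, 2
    amplicon: tuple[int, int] | None = None              # 1-based inclusive
    strand_bias: float = 2.0        # indel-rate multiplier on reverse reads
    bias_sigma: float = 0.0         # log-normal amplification bias


@dataclass
class RecombinantConfig:
    parent_family_a: str
    parent_family_b: str
    breakpoint: int                  # 1-based; sequence = a[1..b] + b[b+1..L]


@dataclass
class SimConfig:
    seed: int = 0
    families: list[FamilyConfig] = field(default_factory=lambda: [
        FamilyConfig(name="F1"),
        FamilyConfig(name="F2", parent="F1", target_ks_between=0.16),
    ])
    exon_lengths: list[int] = field(default_factory=lambda: [150, 300, 240])
    intron_lengths: list[int] = field(default_factory=lambda: [90, 90])
    recombinants: list[RecombinantConfig] = field(default_factory=list)
    deletions: list[tuple[str, int, int, int]] = field(default_factory=list)
    # (family, copy_index, 1-based start on the genomic sequence, length)
    clone_sampling: int = 6
    read_sim: ReadSimConfig = field(default_factory=ReadSimConfig)
    samples: int = 3

    def __post_init__(self):
        rs = self.read_sim
        for r, nm in ((rs.sub_rate, "sub_rate"), (rs.indel_rate, "indel_rate")):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{nm} must be in [0,1]")
        for f in self.families:
            if f.omega <= 0:
                raise ValueError(f"{f.name}: omega must be > 0")
            for t in (f.target_ks_within, f.target_ks_between):
                if t < 0:
                    raise ValueError(f"{f.name}: negative Ks target")
                if t > 3:
                    raise ValueError(f"{f.name}: Ks target {t} > 3 is infeasible")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one intron length per internal exon junction")
        if sum(self.exon_lengths) % 3:
            raise ValueError("exon lengths must concatenate to whole codons")

    def annotation(self) -> ReferenceAnnotation:
        exons = []
        pos = 1
        for i, el in enumerate(self.exon_lengths):
            exons.append((pos, pos + el - 1))
            pos += el
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return ReferenceAnnotation(locus="simlocus", reference_id="simref",
                                   exon_intervals=exons)

    @property
    def locus_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


# ---------------------------------------------------------------------------
# truth containers

@dataclass
class TrueHaplotype:
    name: str
    family: str
    copy_index: int
    sequence: str                    # full genomic sequence


@dataclass
class SimTruth:
    config: SimConfig
    annotation: ReferenceAnnotation
    haplotypes: list[TrueHaplotype]
    family_founders: dict[str, str]
    recombinant_registry: list[dict]
    sample_copies: dict[str, list[str]]
    read_to_source: dict[str, tuple[str, str]] = field(default_factory=dict)
    clone_to_source: dict[str, str] = field(default_factory=dict)

    def by_name(self, name: str) -> TrueHaplotype:
        return next(h for h in self.haplotypes if h.name == name)

    def family_rows(self, family: str) -> list[str]:
        return [h.sequence for h in self.haplotypes if h.family == family]

    def amplicon_of(self, name: str) -> str:
        a = self.config.read_sim.amplicon or (1, self.config.locus_length)
        return self.by_name(name).sequence[a[0] - 1:a[1]]


# ---------------------------------------------------------------------------
# codon-level evolution

def _realized_ks(idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    SD, _ = _codon.diff_arrays()
    S = _codon.syn_sites_array("unweighted")
    sites = 0.5 * float(S[idx_a].sum() + S[idx_b].sum())
    p = float(SD[idx_a, idx_b].sum()) / sites
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _evolve_cds(cds: str, target_ks: float, omega: float,
                rng: np.random.Generator) -> str:
    """Evolve a CDS to ~target synonymous depth with omega-scaled
    nonsynonymous substitution.

    The synonymous stream is targeted iteratively: random point changes are
    proposed in batches, only synonymous (non-stop) ones applied, and the
    realized Jukes-Cantor-corrected Ks is re-measured until it reaches the
    target (5% band, at most 50 rounds).  The nonsynonymous stream is drawn
    independently as Poisson(omega * t * N_sites) accepted amino-acid
    changes at the same per-site intensity t = target Ks.  Keeping the two
    streams independent preserves the Poisson structure of replacement
    counts that neutrality tests rely on; a stop-conditioned joint stream
    would pin the synonymous count and overdisperse the nonsynonymous one.
    Mutations creating stop codons are always rejected.
    """
    if target_ks <= 0:
        return cds
    if target_ks > 3:
        raise ValueError(f"Ks target {target_ks} > 3 is infeasible")
    anc = _codon.codon_index_vector([cds[i:i + 3] for i in range(0, len(cds), 3)])
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    n_cod = len(codons)
    AA, STOPS = _codon.AA, _codon.STOP_CODONS
    p_target = 0.75 * (1.0 - math.exp(-4.0 * target_ks / 3.0))

    def propose():
        ci = int(rng.integers(n_cod))
        pos = int(rng.integers(3))
        old = codons[ci]
        alts = [b for b in "ACGT" if b != old[pos]]
        new = old[:pos] + alts[int(rng.integers(3))] + old[pos + 1:]
        return ci, old, new

    # synonymous stream: iterate batches against the measured realized Ks
    for _ in range(50):
        idx = _codon.codon_index_vector(codons)
        ks = _realized_ks(idx, anc)
        if ks >= 0.95 * target_ks:
            break
        p_cur = 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0)) if math.isfinite(ks) else p_target
        # needed syn subs ~= gap * S_sites with S_sites ~= (3n)/4, and ~1/4 of
        # random proposals are synonymous: proposals ~= gap * 3n; damp by 1/2
        batch = max(1, int(0.5 * (p_target - p_cur) * 3 * n_cod))
        for _ in range(batch):
            ci, old, new = propose()
            if new in STOPS or AA[new] != AA[old]:
                continue
            codons[ci] = new

    # nonsynonymous stream: Poisson count at relative rate omega
    S = _codon.syn_sites_array("unweighted")
    idx = _codon.codon_index_vector(codons)
    n_sites = 3.0 * n_cod - float(S[idx].sum())
    n_non = int(rng.poisson(omega * target_ks * n_sites))
    applied = 0
    guard = 0
    while applied < n_non and guard < 100 * (n_non + 1):
        guard += 1
        ci, old, new = propose()
        if new in STOPS or AA[new] == AA[old]:
            continue
        codons[ci] = new
        applied += 1
    return "".join(codons)


def _evolve_locus(cds: str, introns: list[str], target_ks: float, omega: float,
                  rng: np.random.Generator) -> tuple[str, list[str]]:
    """Evolve coding and intron sequence together.

    The CDS is evolved to the target synonymous depth; introns are then
    mutated neutrally at the depth the coding stream actually realized (the
    iterative targeting can overshoot its nominal increment, and silent-site
    pooling downstream expects introns to track synonymous sites).
    """
    new_cds = _evolve_cds(cds, target_ks, omega, rng)
    ia = _codon.codon_index_vector([cds[i:i + 3] for i in range(0, len(cds), 3)])
    ib = _codon.codon_index_vector([new_cds[i:i + 3] for i in range(0, len(new_cds), 3)])
    achieved = _realized_ks(ia, ib) if target_ks > 0 else 0.0
    if not math.isfinite(achieved):
        achieved = target_ks
    new_introns = [_mutate_neutral(s, achieved, rng) for s in introns]
    return new_cds, new_introns


def _mutate_neutral(seq: str, depth: float, rng: np.random.Generator) -> str:
    """Neutral substitution at JC depth ``depth`` (per-site expected p)."""
    if depth <= 0 or not seq:
        return seq
    p = 0.75 * (1.0 - math.exp(-4.0 * depth / 3.0))
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    codes = np.searchsorted(_BASES, arr)
    hit = rng.random(len(arr)) < p
    shift = rng.integers(1, 4, size=len(arr))
    codes = np.where(hit, (codes + shift) % 4, codes)
    return _BASES[codes].tobytes().decode()


def _random_founder(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, list[str]]:
    """(CDS of random sense codons, intron sequences)."""
    n_cod = sum(cfg.exon_lengths) // 3
    cds = "".join(_codon.SENSE_CODONS[int(i)]
                  for i in rng.integers(0, _codon.N_SENSE, size=n_cod))
    introns = ["".join("ACGT"[int(i)] for i in rng.integers(0, 4, size=ln))
               for ln in cfg.intron_lengths]
    return cds, introns


def _assemble(cfg: SimConfig, cds: str, introns: list[str]) -> str:
    parts = []
    pos = 0
    for i, el in enumerate(cfg.exon_lengths):
        parts.append(cds[pos:pos + el])
        pos += el
        if i < len(introns):
            parts.append(introns[i])
    return "".join(parts)


def _split(cfg: SimConfig, genomic: str) -> tuple[str, list[str]]:
    cds_parts, introns = [], []
    pos = 0
    for i, el in enumerate(cfg.exon_lengths):
        cds_parts.append(genomic[pos:pos + el])
        pos += el
        if i < len(cfg.intron_lengths):
            il = cfg.intron_lengths[i]
            introns.append(genomic[pos:pos + il])
            pos += il
    return "".join(cds_parts), introns


def make_recombinant(a: str, b: str, breakpoint: int) -> str:
    """a[1..breakpoint] ++ b[breakpoint+1..L]; sequences must align 1:1."""
    if len(a) != len(b):
        raise ValueError("parents must have the same aligned length")
    if not 1 <= breakpoint < len(a):
        raise ValueError(f"breakpoint {breakpoint} out of range 1..{len(a) - 1}")
    return a[:breakpoint] + b[breakpoint:]


def simulate_family_set(cfg: SimConfig) -> SimTruth:
    """Generate founders, family copies, configured deletions and recombinants."""
    rng = _substream(cfg.seed, "truth", 0)
    root_cds, root_introns = _random_founder(cfg, rng)
    founders: dict[str, tuple[str, list[str]]] = {}
    copy_cds: dict[str, list[str]] = {}
    haplotypes: list[TrueHaplotype] = []

    def make_copies(fam, cds, introns):
        half = fam.target_ks_within / 2.0
        return [_evolve_locus(cds, introns, half, fam.omega, rng)
                for _ in range(fam.n_copies)]

    def mean_copy_ks(copies_a: list[tuple[str, list[str]]],
                     copies_b: list[tuple[str, list[str]]]) -> float:
        """Mean pairwise silent (synonymous + noncoding) Ks between copy sets —
        the same pooled quantity the statistics module reports."""
        SD, _ = _codon.diff_arrays()
        S = _codon.syn_sites_array("unweighted")
        vals = []
        for cds_a, intr_a in copies_a:
            ia = _codon.codon_index_vector(
                [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)])
            na = "".join(intr_a)
            for cds_b, intr_b in copies_b:
                ib = _codon.codon_index_vector(
                    [cds_b[i:i + 3] for i in range(0, len(cds_b), 3)])
                nb = "".join(intr_b)
                diffs = float(SD[ia, ib].sum()) + sum(x != y for x, y in zip(na, nb))
                sites = 0.5 * float(S[ia].sum() + S[ib].sum()) + len(na)
                p = diffs / sites
                vals.append(math.inf if p >= 0.75
                            else -0.75 * math.log1p(-4.0 * p / 3.0))
        return float(np.mean(vals))

    for fam in cfg.families:
        if fam.parent is None:
            base_cds, base_introns = root_cds, root_introns
        else:
            if fam.parent not in founders:
                raise ValueError(f"{fam.name}: parent {fam.parent!r} not defined before it")
            base_cds, base_introns = founders[fam.parent]
        cds, introns = base_cds, list(base_introns)
        copies = make_copies(fam, cds, introns)
        if fam.parent is not None and fam.target_ks_between > 0:
            # target_ks_between is the expected copy-level between-family Ks.
            # The JC estimator is not additive over branches at these depths,
            # so the founder is topped up until the realized copy-to-copy Ks
            # against the parent family reaches the target.
            parent_copies = copy_cds[fam.parent]
            for _ in range(12):
                realized = mean_copy_ks(copies, parent_copies)
                if realized >= 0.95 * fam.target_ks_between:
                    break
                gap = fam.target_ks_between - realized
                cds, introns = _evolve_locus(cds, introns, 0.7 * gap, fam.omega, rng)
                copies = make_copies(fam, cds, introns)
        founders[fam.name] = (cds, introns)
        copy_cds[fam.name] = list(copies)
        for k, (ccds, cintrons) in enumerate(copies):
            haplotypes.append(TrueHaplotype(
                name=f"{fam.name}.c{k + 1}", family=fam.name, copy_index=k,
                sequence=_assemble(cfg, ccds, cintrons)))

    for fam_name, copy_idx, start, length in cfg.deletions:
        hap = next(h for h in haplotypes
                   if h.family == fam_name and h.copy_index == copy_idx)
        s = hap.sequence
        hap.sequence = s[:start - 1] + s[start - 1 + length:]

    registry = []
    for i, rc in enumerate(cfg.recombinants):
        a = next(h for h in haplotypes if h.family == rc.parent_family_a)
        b = next(h for h in haplotypes if h.family == rc.parent_family_b)
        seq = make_recombinant(a.sequence, b.sequence, rc.breakpoint)
        name = f"R{i + 1}.{rc.parent_family_a}x{rc.parent_family_b}"
        haplotypes.append(TrueHaplotype(name=name, family="recombinant",
                                        copy_index=i, sequence=seq))
        registry.append({"name": name, "parent_a": a.name, "parent_b": b.name,
                         "breakpoint": rc.breakpoint})

    sample_ids = [f"S{i + 1}" for i in range(cfg.samples)]
    sample_copies = {sid: [h.name for h in haplotypes] for sid in sample_ids}
    return SimTruth(config=cfg, annotation=cfg.annotation(), haplotypes=haplotypes,
                    family_founders={k: _assemble(cfg, *v) for k, v in founders.items()},
                    recombinant_registry=registry, sample_copies=sample_copies)


# ---------------------------------------------------------------------------
# reads and clones

def _apply_read_errors(seq: str, eps: float, indel_rate: float,
                       len_probs: tuple[float, float],
                       rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    codes = np.searchsorted(_BASES, arr)
    L = len(codes)
    if eps > 0:
        hit = rng.random(L) < eps
        shift = rng.integers(1, 4, size=L)
        codes = np.where(hit, (codes + shift) % 4, codes)
    if indel_rate > 0:
        pos = np.nonzero(rng.random(L) < indel_rate)[0]
        if len(pos):
            out = []
            prev = 0
            for p in pos:
                out.append(codes[prev:p])
                ln = 1 if rng.random() < len_probs[0] else 2
                if rng.random() < 0.5:   # deletion
                    prev = min(p + ln, L)
                else:                    # insertion of uniform random bases
                    out.append(np.asarray(rng.integers(0, 4, size=ln)))
                    prev = p
            out.append(codes[prev:])
            codes = np.concatenate(out)
    return _BASES[codes].tobytes().decode()


def _copy_weights(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.lognormal(mean=0.0, sigma=sigma, size=n) if sigma > 0 else np.ones(n)
    return w / w.sum()


def simulate_reads(truth: SimTruth, cfg: SimConfig | None = None):
    """Amplicon reads per sample with substitution and strand-biased indel errors.

    Returns (reads_by_sample, read_to_source) where read_to_source maps the
    read id to (true haplotype name, strand).  Reverse-strand reads are
    emitted reverse-complemented, with the indel rate multiplied by the
    configured strand-bias factor.  Also recorded on ``truth``.
    """
    cfg = cfg or truth.config
    rs = cfg.read_sim
    amp = rs.amplicon or (1, cfg.locus_length)
    if amp[0] < 1:
        raise ValueError("amplicon interval outside locus")
    q = 40 if rs.sub_rate <= 0 else min(40, int(round(-10 * math.log10(rs.sub_rate))))
    reads_by_sample: dict[str, list[SeqRecord]] = {}
    read_to_source: dict[str, tuple[str, str]] = {}
    for sid in sorted(truth.sample_copies):
        rng = _substream(cfg.seed, sid, 1)
        hap_names = truth.sample_copies[sid]
        templates = [truth.by_name(nm).sequence[amp[0] - 1:amp[1]] for nm in hap_names]
        weights = _copy_weights(len(hap_names), rs.bias_sigma, rng)
        depth = int(rng.poisson(rs.depth_mean))
        picks = rng.choice(len(hap_names), size=depth, p=weights)
        recs = []
        for i, hi in enumerate(picks):
            reverse = rng.random() < 0.5
            irate = rs.indel_rate * (rs.strand_bias if reverse else 1.0)
            seq = _apply_read_errors(templates[hi], rs.sub_rate, irate,
                                     rs.indel_len_probs, rng)
            if reverse:
                seq = revcomp(seq)
            rid = f"{sid}:r{i:05d}"
            recs.append(SeqRecord(id=rid, sample_id=sid, nucleotides=seq,
                                  qualities=[q] * len(seq), evidence_source="MPS"))
            read_to_source[rid] = (hap_names[hi], "-" if reverse else "+")
        reads_by_sample[sid] = recs
    truth.read_to_source = read_to_source
    return reads_by_sample, read_to_source


def simulate_clones(truth: SimTruth, cfg: SimConfig | None = None,
                    pools: dict[str, list[str]] | None = None):
    """Error-free full-length clone (Sanger) sampling per sample or pool.

    Draws ``clone_sampling`` clones per unit with the same amplification-
    bias model as the reads; Sanger chemistry is treated as exact.
    """
    cfg = cfg or truth.config
    units = pools or {sid: [sid] for sid in sorted(truth.sample_copies)}
    clones: list[SeqRecord] = []
    clone_to_source: dict[str, str] = {}
    for unit in sorted(units):
        rng = _substream(cfg.seed, unit, 2)
        hap_names = sorted({nm for sid in units[unit]
                            for nm in truth.sample_copies[sid]})
        weights = _copy_weights(len(hap_names), cfg.read_sim.bias_sigma, rng)
        picks = rng.choice(len(hap_names), size=cfg.clone_sampling, p=weights)
        for i, hi in enumerate(picks):
            cid = f"{unit}:clone{i + 1}"
            clones.append(SeqRecord(
                id=cid, sample_id=unit,
                nucleotides=truth.by_name(hap_names[hi]).sequence,
                evidence_source="PCS"))
            clone_to_source[cid] = hap_names[hi]
    truth.clone_to_source = clone_to_source
    return clones, clone_to_source
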