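"""Haplotype calling: Poisson error model, validation cascade, evidence stats."""

import numpy as np
import pytest

from lucfam import hapcall, synthdata as sd
from lucfam.core import ReferenceAnnotation, SeqRecord
from lucfam.hapcall import (Haplotype, apply_validation_cascade, build_registry,
                            call_candidates, call_samples,
                            correlate_clone_read_support, error_posterior,
                            filter_reads, mutation_profile_statistic)


def _reads(seqs, sample="S1"):
    return [SeqRecord(id=f"{sample}:r{i}", sample_id=sample, nucleotides=s,
                      evidence_source="MPS") for i, s in enumerate(seqs)]


def _rand_seq(rng, L=300):
    return "".join(rng.choice(list("ACGT"), L))


class TestFilterReads:
    def test_length_boundary(self):
        reads = _reads(["A" * 150, "A" * 151, "A" * 300])
        kept, stats = filter_reads(reads)
        assert stats == {"input": 3, "kept": 2, "discarded": 1}

    def test_all_short_warns(self):
        with pytest.warns(UserWarning):
            kept, _ = filter_reads(_reads(["A" * 100] * 5))
        assert kept == []


class TestErrorModel:
    def test_poisson_arithmetic(self):
        """Parent n=1000, eps=0.005, L=300, k=1: lambda ~ 0.372; a count of
        12 is far beyond error expectation, a singleton is not."""
        lam, post = error_posterior(1000, 12, 1, 300, 0.005)
        assert lam == pytest.approx(0.372, abs=5e-3)
        assert post > 0.999
        lam1, post1 = error_posterior(1000, 1, 1, 300, 0.005)
        assert post1 == pytest.approx(np.exp(-lam1))
        assert post1 == pytest.approx(0.689, abs=5e-3)
        assert post1 <= 0.95

    def test_caller_applies_model(self):
        rng = np.random.default_rng(0)
        parent = _rand_seq(rng)
        mut = parent[:10] + ("A" if parent[10] != "A" else "C") + parent[11:]
        ref = SeqRecord(id="ref", nucleotides=parent, evidence_source="REF")
        # abundant 1-off variant: accepted as its own candidate
        cands = call_candidates(_reads([parent] * 1000 + [mut] * 12), ref, eps=0.005)
        assert {c.sequence for c in cands} == {parent, mut}
        # singleton 1-off variant: absorbed into the parent
        cands = call_candidates(_reads([parent] * 1000 + [mut]), ref, eps=0.005)
        assert {c.sequence for c in cands} == {parent}
        assert cands[0].total_reads == 1001

    def test_single_unique_sequence(self):
        ref = SeqRecord(id="ref", nucleotides="ACGT" * 50, evidence_source="REF")
        cands = call_candidates(_reads(["ACGT" * 50] * 7), ref, eps=0.01)
        assert len(cands) == 1
        assert cands[0].posterior_score == 1.0

    def test_bad_eps_rejected(self):
        ref = SeqRecord(id="ref", nucleotides="ACGT" * 50, evidence_source="REF")
        for eps in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                call_candidates(_reads(["ACGT" * 50]), ref, eps=eps)

    def test_read_conservation(self):
        rng = np.random.default_rng(1)
        parent = _rand_seq(rng)
        seqs = [parent] * 50
        for _ in range(30):   # sprinkle random 1-2 edit variants
            pos = int(rng.integers(300))
            base = "ACGT"[int(rng.integers(4))]
            seqs.append(parent[:pos] + base + parent[pos + 1:])
        ref = SeqRecord(id="ref", nucleotides=parent, evidence_source="REF")
        cands = call_candidates(_reads(seqs), ref, eps=0.01)
        assert sum(c.total_reads for c in cands) == len(seqs)


def _plain_hap(seq, counts, samples=None, posterior=1.0):
    return Haplotype(sequence=seq, read_counts=dict(counts),
                     samples_observed=set(samples or counts),
                     posterior_score=posterior)


class TestValidationCascade:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.ref_seq = _rand_seq(rng, 120)
        self.ref = SeqRecord(id="amp", nucleotides=self.ref_seq,
                             evidence_source="REF")

    def _variant(self, pos):
        base = "A" if self.ref_seq[pos] != "A" else "C"
        return self.ref_seq[:pos] + base + self.ref_seq[pos + 1:]

    def test_frequency_rule_with_multisample_rescue(self):
        """A=80 kept outright, B=12 rescued by a second sample, C=8 dropped."""
        A = _plain_hap(self.ref_seq, {"S1": 80, "S2": 200})
        B = _plain_hap(self._variant(10), {"S1": 12, "S2": 30}, {"S1", "S2"})
        C = _plain_hap(self._variant(20), {"S1": 8})
        accepted, audit = apply_validation_cascade([A, B, C], [], self.ref)
        seqs = {h.sequence for h in accepted}
        assert A.sequence in seqs and B.sequence in seqs
        assert C.sequence not in seqs
        assert "MULTI_SAMPLE" in B.flags
        assert any(a.stage == "frequency" for a in audit)

    def test_posterior_threshold(self):
        A = _plain_hap(self.ref_seq, {"S1": 80})
        low = _plain_hap(self._variant(5), {"S1": 40}, posterior=0.90)
        accepted, audit = apply_validation_cascade([A, low], [], self.ref)
        assert {h.sequence for h in accepted} == {A.sequence}
        assert audit[0].stage == "posterior"

    def test_indel_requires_clone_support(self):
        """A clone-matched 2-nt deletion passes; a novel 1-nt insertion is
        dropped regardless of frequency."""
        deleted = self.ref_seq[:50] + self.ref_seq[52:]
        inserted = self.ref_seq[:80] + "A" + self.ref_seq[80:]
        A = _plain_hap(self.ref_seq, {"S1": 50})
        D = _plain_hap(deleted, {"S1": 40})
        I = _plain_hap(inserted, {"S1": 60})
        clone = SeqRecord(id="P1:clone1", sample_id="P1", nucleotides=deleted,
                          evidence_source="PCS")
        accepted, audit = apply_validation_cascade([A, D, I], [clone], self.ref)
        seqs = {h.sequence for h in accepted}
        assert deleted in seqs and inserted not in seqs
        assert "HAS_SHORT_INDEL" in D.flags

    def test_no_clones_disables_indel_exception(self):
        deleted = self.ref_seq[:50] + self.ref_seq[52:]
        A = _plain_hap(self.ref_seq, {"S1": 50})
        D = _plain_hap(deleted, {"S1": 40})
        accepted, _ = apply_validation_cascade([A, D], [], self.ref)
        assert {h.sequence for h in accepted} == {self.ref_seq}

    def test_premature_stop_requires_clone_support(self):
        # coding reference without stops, then implant TAA at codon 5
        cds = "GGC" * 40
        ref = SeqRecord(id="amp", nucleotides=cds, evidence_source="REF")
        annot = ReferenceAnnotation("l", "amp", [(1, 120)])
        stopped = cds[:12] + "TAA" + cds[15:]
        A = _plain_hap(cds, {"S1": 60})
        S = _plain_hap(stopped, {"S1": 40})
        accepted, _ = apply_validation_cascade([A, S], [], ref, annot=annot)
        assert {h.sequence for h in accepted} == {cds}
        clone = SeqRecord(id="c", sample_id="P", nucleotides=stopped,
                          evidence_source="PCS")
        A2 = _plain_hap(cds, {"S1": 60})
        S2 = _plain_hap(stopped, {"S1": 40})
        accepted, _ = apply_validation_cascade([A2, S2], [clone], ref, annot=annot)
        assert stopped in {h.sequence for h in accepted}

    def test_pcs_match_rescues_low_frequency(self):
        A = _plain_hap(self.ref_seq, {"S1": 95})
        rare = _plain_hap(self._variant(30), {"S1": 5})
        clone = SeqRecord(id="c", sample_id="P", nucleotides=rare.sequence,
                          evidence_source="PCS")
        accepted, _ = apply_validation_cascade([A, rare], [clone], self.ref)
        assert rare.sequence in {h.sequence for h in accepted}
        assert "PCS_MATCHED" in rare.flags

    def test_min_freq_monotonicity(self):
        A = _plain_hap(self.ref_seq, {"S1": 70})
        B = _plain_hap(self._variant(3), {"S1": 20})
        C = _plain_hap(self._variant(7), {"S1": 10})
        sizes = []
        for f in (0.05, 0.15, 0.25):
            acc, _ = apply_validation_cascade(
                [_plain_hap(h.sequence, h.read_counts) for h in (A, B, C)],
                [], self.ref, min_freq=f)
            sizes.append(len(acc))
        assert sizes == sorted(sizes, reverse=True)

    def test_adding_clone_never_shrinks(self):
        A = _plain_hap(self.ref_seq, {"S1": 90})
        B = _plain_hap(self._variant(3), {"S1": 10})
        acc0, _ = apply_validation_cascade(
            [_plain_hap(h.sequence, h.read_counts) for h in (A, B)], [], self.ref)
        clone = SeqRecord(id="c", sample_id="P", nucleotides=B.sequence,
                          evidence_source="PCS")
        acc1, _ = apply_validation_cascade(
            [_plain_hap(h.sequence, h.read_counts) for h in (A, B)], [clone], self.ref)
        assert {h.sequence for h in acc0} <= {h.sequence for h in acc1}


class TestOracleEquivalence:
    def test_error_free_reads_recover_truth_exactly(self):
        cfg = sd.SimConfig(seed=21, families=[
            sd.FamilyConfig(name="F1", n_copies=3, target_ks_within=0.15,
                            omega=0.05)],
            samples=2,
            read_sim=sd.ReadSimConfig(depth_mean=300, sub_rate=0.0,
                                      indel_rate=0.0, amplicon=(1, 360)))
        truth = sd.simulate_family_set(cfg)
        reads, _ = sd.simulate_reads(truth)
        ref = SeqRecord(id="amp", nucleotides=truth.family_founders["F1"][:360],
                        evidence_source="REF")
        cands = call_samples(reads, ref, eps=1e-3)
        accepted, _ = apply_validation_cascade(cands, [], ref)
        true_set = {truth.amplicon_of(h.name) for h in truth.haplotypes}
        assert {h.sequence for h in accepted} == true_set


class TestMutationProfile:
    def _hap(self, seq, samples):
        return Haplotype(sequence=seq, read_counts={s: 10 for s in samples},
                         samples_observed=set(samples))

    def test_hand_counted_means(self):
        """Strong nearest-distances {2,2,4}; one weak at 3: means 2.67 vs 3.0."""
        base = "A" * 20
        s1 = base
        s2 = "TT" + base[2:]                          # 2 from s1
        s3 = base[:10] + "CCCC" + base[14:]           # 4 from s1, 6 from s2
        w1 = base[:5] + "GGG" + base[8:]              # 3 from s1
        res = mutation_profile_statistic([
            self._hap(s1, ["a", "b"]), self._hap(s2, ["a", "b"]),
            self._hap(s3, ["a", "c"]), self._hap(w1, ["a"])])
        assert res.strong_mean == pytest.approx(8 / 3)
        assert res.weak_mean == pytest.approx(3.0)
        assert res.n_strong == 3 and res.n_weak == 1

    def test_empty_weak_set(self):
        base = "A" * 20
        res = mutation_profile_statistic([
            self._hap(base, ["a", "b"]),
            self._hap("T" + base[1:], ["a", "b"])])
        assert res.weak_mean is None
        assert res.strong_mean == pytest.approx(1.0)

    def test_small_strong_set_undefined(self):
        res = mutation_profile_statistic([self._hap("A" * 20, ["a"])])
        assert res.strong_mean is None
        assert "undefined" in res.verdict

    def test_simulated_true_weak_haplotypes_look_like_strong(self):
        """When weakly supported haplotypes are genuine alleles their mutation
        profile matches the strongly supported set (within 1 SE)."""
        cfg = sd.SimConfig(seed=33, families=[
            sd.FamilyConfig(name="F1", n_copies=8, target_ks_within=0.05,
                            omega=0.5)], samples=2)
        truth = sd.simulate_family_set(cfg)
        haps = []
        for i, h in enumerate(truth.haplotypes):
            samples = ["a", "b"] if i < 5 else ["a"]   # last three 'weak'
            haps.append(self._hap(h.sequence[:400], samples))
        res = mutation_profile_statistic(haps)
        spread = np.hypot(res.weak_se or 0.0, res.strong_se or 0.0)
        assert abs(res.weak_mean - res.strong_mean) <= 2 * max(spread, 1e-9) or \
            res.p_value > 0.05


class TestCloneReadCorrelation:
    def _registry(self, pts):
        from lucfam.hapcall import EvidenceRegistry, RegistryEntry
        reg = EvidenceRegistry(locus="l")
        for i, (reads, clones) in enumerate(pts):
            reg.entries.append(RegistryEntry(
                sequence=f"s{i}", names=[], sources={"PCS", "MPS"},
                clone_count=clones, read_counts={"S1": reads},
                samples_observed={"S1"}))
        return reg

    def test_proportional_counts(self):
        assert correlate_clone_read_support(
            self._registry([(10, 1), (20, 2), (40, 4)])) == pytest.approx(1.0)

    def test_hand_ols(self):
        r2 = correlate_clone_read_support(self._registry([(10, 1), (20, 2), (35, 3)]))
        assert r2 == pytest.approx(0.98684, abs=1e-4)

    def test_constant_clone_counts(self):
        assert correlate_clone_read_support(
            self._registry([(10, 2), (20, 2), (30, 2)])) == 0.0

    def test_too_few_points(self):
        assert correlate_clone_read_support(self._registry([(10, 1), (20, 2)])) is None


def test_registry_matches_over_sequenced_segment():
    """One sequenced-segment haplotype can gather several full-length clones."""
    rng = np.random.default_rng(4)
    amp = _rand_seq(rng, 100)
    ref = SeqRecord(id="amp", nucleotides=amp, evidence_source="REF")
    h = Haplotype(sequence=amp, read_counts={"S1": 50}, samples_observed={"S1"})
    # two clones differing only outside the amplicon
    tail1, tail2 = _rand_seq(rng, 80), _rand_seq(rng, 80)
    clones = [SeqRecord(id=f"P:c{i}", sample_id="P", nucleotides=amp + t,
                        evidence_source="PCS") for i, t in enumerate([tail1, tail2])]
    reg = build_registry([h], clones, ref)
    entry = next(e for e in reg.entries if e.sequence == amp)
    assert entry.clone_count == 2
    assert entry.sources == {"MPS", "PCS"}
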