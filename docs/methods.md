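# Methods

This note documents the models, estimators and numerical choices behind
`lucfam`, and what the synthetic-data generator does and does not emulate.

## Coordinates, alignment and site classes

All genomic coordinates are 1-based inclusive intervals, following the
GenBank feature convention of the reference sequences this kind of study
annotates against. Sequences are handled plus-strand; read orientation is
normalized once at intake by comparing the edit distance of each read and
its reverse complement to the reference.

`anchor_align` aligns each member pairwise to a single reference (global
affine alignment; defaults match = 2, mismatch = −3, gap open = −8, gap
extend = −1) and merges the results on reference coordinates. Columns
absent from the reference (insertions) are appended after the reference
position they follow; members inserting at the same position share a
left-justified insertion block. Ungapping any member row recovers its
input exactly — this round trip is enforced by tests. Terminal gaps are
free by default, which is correct for amplicon reads and truncated clones
that cover only part of the reference; for full-length, highly diverged
haplotypes free ends must be disabled (`free_end_gaps=False`), because at
≳45% nucleotide divergence the expected per-base alignment score turns
negative and the aligner would silently leave low-identity flanks
unaligned, biasing divergence estimates downward. Members below 50%
identity over their aligned span are flagged unalignable and excluded with
a warning.

`build_site_mask` classifies columns as coding (inside exons, with codon
frame from the concatenated exons), noncoding (introns) or excluded
(outside the analysed segment, inside primer spans or listed exclusion
intervals, or insertion columns). A codon touching any excluded column is
dropped whole rather than partially counted; this keeps the per-codon
site decomposition exactly conservative (s + n = 3) and mirrors the
complete-deletion treatment of alignment gaps. The analysed segment is
explicit configuration rather than a hard-coded coordinate, so a segment
described from either end of a reference can be expressed unambiguously.

## Nei–Gojobori counting

Synonymous site fractions are computed per codon position as the share of
the three possible changes that preserve the amino acid; the weighted
("modified") scheme weights each change by R = 2 when it is a transition.
Changes creating stop codons count as nonsynonymous. Pairwise differences
enumerate all k! mutational pathways between codons differing at k
positions, discard pathways passing through stop codons, and average the
synonymous/nonsynonymous split over the survivors; when every pathway is
blocked the differences are counted as all nonsynonymous. Both tables are
precomputed over the 61 sense codons and verified exhaustively against an
independent brute-force enumerator in the tests.

Convention: the unweighted scheme is used for diversity, divergence and
the MK test (the convention of standard population-genetics software);
the weighted scheme is reserved for phylogenetic synonymous distances,
where the transition/transversion bias of 2 is part of the distance
definition.

## Diversity, divergence and neutrality statistics

Nucleotide diversity is Nei's π computed separately at silent sites — the
pool of fractional synonymous sites plus noncoding columns — and at
nonsynonymous sites. Gap/ambiguity handling is complete deletion: any
column carrying a non-ACGT character in any analysed sequence is removed,
and a codon column triple is usable only when **every** sequence carries a
sense codon there (this also protects against rare alignment-induced
frame disruptions presenting as stop codons). The per-pair proportion of
differences is Jukes–Cantor corrected, then averaged over pairs;
correcting the averaged proportion instead is available as a flag and
differs only in the third decimal at these divergences. Saturated pairs
(p ≥ 0.75) are excluded from divergence means with a warning.

Haplotype diversity is the sample-size-corrected `Hd = n/(n−1)(1 − Σ pᵢ²)`.
Tajima's D uses the standard 1989 constants over all usable (coding and
noncoding) columns and is reported as undefined — not zero — when there
are no segregating sites.

The McDonald–Kreitman table counts, per codon, segregating changes within
the ingroup (each distinct non-consensus codon against the ingroup
consensus, pathway-averaged) and fixed differences at positions
monomorphic in both groups with different states; a position both
segregating and divergent counts once, as polymorphic. Noncoding
positions contribute to the silent cells the same way. Fractional
pathway-averaged counts are rounded to the nearest integer per cell at
the end. Significance is the two-tailed Fisher's exact probability;
`NI = (Pn·Ds)/(Ps·Dn)` is reported whenever Ps > 0 and Dn > 0. At
outgroup divergences beyond Ks ≈ 0.3 the test inherits the well-known
anti-conservative bias from synonymous-site saturation; the type-I error
simulation therefore runs at the divergence scale the test is meant for
(Ks ≈ 0.2, matching interspecific contrasts in this gene family).

## Haplotype calling and the validation cascade

Candidates are exact dereplicated read sequences per sample, processed in
decreasing abundance. For candidate `c` (count `n_c`, length `L`) whose
nearest more-abundant accepted parent `p` has count `n_p` at edit distance
`k`, the expected count of reads from `p` that are exactly `c` under a
uniform substitution-error rate ε is `λ = n_p (ε/3)^k (1−ε)^(L−k)`; the
posterior score is `P(N < n_c | N ~ Poisson(λ))` and candidates scoring
≤ 0.95 are merged into their parent, counts added. Two boundary rules
complete the model: the most abundant candidate per sample is always
accepted, and a singleton with any more-abundant accepted parent is always
absorbed into its nearest parent. The singleton rule is the limiting
behaviour of the conditioned (observed-at-least-once) abundance p-value
used by modern amplicon denoisers: with a single observation the error
hypothesis can never be rejected, whereas the unconditioned score tends to
1 as λ → 0 and would accept every unique error read. Absorption is what
lets true haplotypes accumulate their error-read clouds and emerge with
realistic frequencies.

The cascade then applies, in order: the posterior threshold (> 0.95);
rejection of candidates with 1–2 nt indels relative to the reference
unless an identical indel (position, length, inserted bases) occurs in a
cloned sequence (indels are extracted from an affine-gap alignment, not a
unit-cost edit path, so adjacent substitutions are never misread as paired
indels); rejection of premature stop codons unless present in a clone;
and a 15% per-sample read-frequency floor, waived for candidates whose
sequence matches a clone over the sequenced segment or that were observed
in ≥ 2 samples. Frequency denominators are the read totals of candidates
still alive at the frequency stage, and every drop is logged with the rule
that fired. Clone/MPS identity is evaluated over the sequenced (amplicon)
segment only, located in each full-length clone by infix alignment.

Supporting-evidence statistics: the mutation-profile comparison contrasts
the nearest-neighbour distances of weakly supported haplotypes (single
sample, no clone match) against the strongly supported set, with a
two-sided Welch test; clone/read support agreement is the R² of an
ordinary least-squares fit of clone counts on read counts.

## Family assignment and mosaic detection

Diagnostic sites are columns fixed within each of two families and
different between them (gap/ambiguous columns skipped). Haplotypes are
labelled by majority vote over covered diagnostic sites, with scores below
0.8 labelled ambiguous. Mosaic detection scans all single breakpoints
between adjacent diagnostic sites and all ordered label pairs (identical
labels allowed, so the two-segment optimum can never exceed the
single-label discordance); a haplotype is mosaic when the two-segment
labelling saves at least `min_gain = 3` discordant sites — three being the
number of exclusive shared variants that distinguished convincing
recombinant lineages from artefacts in this gene family. Mosaic-flagged
haplotypes are excluded from diversity and phylogenetic inputs by default
because their segments carry different evolutionary histories.

## Phylogenetics

Synonymous distances use weighted (R = 2) site counts and plain pathway
differences, with pairwise deletion, corrected by the gamma-rate
Jukes–Cantor transform with shape a = 1 (`d = p/(1 − 4p/3)`). Neighbor
joining follows Saitou–Nei with the Studier–Keppler Q criterion; ties
break toward the lowest-index pair, negative branch lengths are clamped to
zero with the deficit recorded, and the result is an unrooted tree with a
trifurcating root node. Bootstrap replicates resample codon columns with
replacement — the resampling unit that preserves codon structure for
synonymous distance computation — and supports are the percentage of
usable replicates containing each original bipartition; replicates with
saturated entries are skipped and counted. NJ is verified against random
additive trees (exact topology and path lengths up to 12 taxa) and
cross-checked against an independent implementation in the tests.

## The synthetic-data generator

The generator emulates the regime observed in a tandem luciferase family:
two to three paralogous families at copy-level silent divergence between
~0.16 and ~0.8, within-family silent diversity ~0.15, nonsynonymous
diversity suppressed by ω ≈ 0.05, occasional recombinant alleles, sparse
error-free clone (Sanger) sampling, and amplicon reads with substitution
errors plus strand-biased 1–2 nt indel errors (indel rate doubled on
reverse-strand reads by default; lengths 1 and 2 with probabilities
0.8/0.2).

Evolution is codon-level with two independent substitution streams. The
synonymous stream is targeted iteratively: random synonymous (non-stop)
changes are applied in damped batches and the realized Jukes–Cantor-
corrected Ks is re-measured until it reaches the target (5% band, ≤ 50
rounds). The nonsynonymous stream is drawn as an independent
Poisson(ω · t · N_sites) number of accepted amino-acid changes at the same
per-site intensity t. Keeping the streams independent preserves the
Poisson structure of replacement counts that neutrality tests rely on; an
earlier joint stream stopped on the realized synonymous count pinned Sd
and made Nd negative-binomially overdispersed, which inflated the MK
type-I error well beyond nominal. Introns evolve neutrally at the depth
the coding stream actually realized, so silent-site pooling downstream
sees consistent synonymous and noncoding divergence.

`target_ks_between` is defined as the expected copy-level silent Ks
between families — the quantity the statistics module measures — and is
realized by topping up the family founder until the realized copy-to-copy
pooled silent Ks against the parent family reaches the target; a fixed
founder-depth formula is not used because Jukes–Cantor-corrected
Nei–Gojobori distances are not additive over branches at these depths.
Recombinants are exact single-breakpoint joins of two parent haplotypes;
structural variation between true haplotypes otherwise enters only
through an explicit configured deletion list. Clones are error-free
full-length copies (Sanger chemistry treated as exact); reads draw their
template copy with optional log-normal amplification bias, per-sample
depth is Poisson, and qualities are emitted consistent with the
substitution rate.

Randomness: one master seed; each (sample, stage) derives its own stream
by hashing, so adding a sample leaves other samples' outputs byte-
identical. What the generator does **not** emulate: flow-space (homopolymer)
signal artefacts of the sequencing platform, quality-score miscalibration,
PCR chimera formation during amplification (available in principle as
recombinant configuration, but off by default), and intron length
polymorphism beyond configured deletions. Passing tests therefore
demonstrate correct recovery under idealized independent-error reads, not
robustness to platform-specific artefact structure.

## Problem sizes used in the test suite

The default locus is 690 nt of coding sequence (230 codons) with two 90-nt
introns. Stochastic checks use: 20 seeds for the π/Ks/ω recovery contrasts
(6 haplotypes each), 20 seeds for haplotype-calling recovery (3 samples ×
~1000 reads of a 360-nt amplicon, 3 copies, ε = 0.01), and 200 seeds for
the MK type-I simulation (450-nt CDS, 6 + 1 sequences). These sizes give
sampling error comfortably inside the asserted tolerances (mean relative
error < 15%, false-haplotype fraction ≤ 5%, rejection rate ≤ 7%) while
keeping the full suite fast enough for routine development.

## Known limitations

* The abundance-parent error model assumes a uniform per-base substitution
  rate; it has no position- or quality-aware error profile.
* The MK cell counts use consensus-anchored pathway averaging with final
  integer rounding; other reasonable pathway/rounding policies can shift
  cells by ±1 at high polymorphism.
* Between-family distances near synonymous saturation (pooled p
  approaching 0.75) are increasingly estimator-limited; targets above
  Ks ≈ 0.8 converge to ~10% below nominal and Ks > 3 is rejected outright.
* Bootstrap supports are computed for the topology of the original tree
  only; alternative splits are counted against it, not summarized.
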