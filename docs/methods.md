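# Methods

This note documents the models behind each module, the tunable
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## The synthetic diploid bundle

The simulator emulates the *data shape* of a single deeply inbred diploid
genome, not its evolutionary history. One scaffold of i.i.d. uniform
bases is decorated in a fixed stage order — gene models, TE bursts,
provirus integrations, then heterozygous variants — with one independent
pseudo-random stream per stage (spawned from the single user seed), so
enabling or resizing one output class never perturbs another. All
decoration is by in-place substitution of the host sequence, which keeps
scaffold lengths and every previously assigned coordinate stable.

**Heterozygosity landscape.** Heterozygous sites are placed by per-base
Bernoulli draws whose probability depends on a two-state (purged /
retained) block process: alternating blocks with geometric lengths, the
two means scaled so the stationary purged fraction equals
`window_purged_fraction`. Defaults are chosen to reproduce the situation
in a heavily inbred genome: retained rate 0.33%, purged rate 0.005%,
purged fraction 60%, giving a genome-wide combined rate near 0.135% with
a strongly bimodal 50 kb window histogram. The block-length scale is not
identifiable from 50 kb windows alone; the default mean of 500 kb makes
most windows state-pure, which is what a bimodal window histogram
requires. SNP alternate alleles are transitions with probability
`ts_fraction` (default 2.54/3.54, i.e. a Ts/Tv of 2.54); InDels are
`indel_fraction` of polymorphisms (default 0.126, the InDel share of a
0.135% combined rate split 0.118/0.017), insertion or deletion with equal
probability, lengths uniform on 1–10 bp (no canonical published length
law at this scale; uniform is deliberately assumption-free). Variants
swallowed by an earlier deletion are dropped; at realistic rates this
loses well under 0.1% of sites.

**Gene models.** Each gene has 2–5 exons whose concatenation (reverse
complemented for minus-strand genes) is an intact ORF: `ATG`, sense
codons only, terminal stop. Intact ORFs make simulated genes usable as
negative controls for pseudogene calling. Exons equal CDS (no UTR);
UTR-containing cases are exercised by hand-built fixtures in the tests
instead.

**TE bursts.** Each burst is (consensus id, copy count, mean divergence,
s.d.); a random 300 bp consensus is drawn per id and each copy is an
independent per-site substitution mutant at its drawn divergence
(uniform among the three alternatives), planted on the plus strand in
unoccupied sequence. Substitution-only mutation means copy length equals
consensus length; indel decay of old copies is not modelled (see
Limitations).

**Proviruses.** A reference "virus" is a set of random component
sequences (LTR 600 bp, gag 1.5 kb, pol 3.6 kb, env 2 kb — a
gammaretrovirus-like ~8.3 kb provirus). Full integrations plant all five
components collinear (`LTR-gag-pol-env-LTR`) on one random strand at 2%
divergence; fragments plant a single truncated component (40–90% of its
length) at 15% divergence, emulating ancient decayed insertions.

**Reads.** Uniformly positioned single-end reads with independent
per-base substitution errors; no quality model, no GC bias, no
duplicates. Paired reads for junction support are proper FR pairs with
Normal insert sizes.

Interval placement is rejection sampling with an explicit free-gap scan
as fallback, so crowded configurations either place deterministically or
fail loudly.

**What passing tests show.** Because the generator knows its truth,
tests demonstrate that each operation recovers planted signal under the
stated noise model. They do not demonstrate robustness to alignment
artefacts, assembly collapse of near-identical repeats, segmental
duplications, or non-uniform base composition — none of which the
generator produces.

## k-mer genome sizing

Canonical k-mers (lexicographic minimum of a window and its reverse
complement, odd k so no window is its own reverse complement) are packed
two bits per base into int64 words and counted with vectorised numpy
passes; windows containing N are skipped. The estimator is the classic
peak-depth method: `G = (k-mer instances above the error cutoff) /
(modal multiplicity)`. The error cutoff defaults to the first local
minimum of the spectrum — the trough between the sequencing-error tail
and the coverage peak — and a monotone (peak-free) spectrum raises
rather than guessing. Default k = 17: large enough that random 17-mer
collisions are negligible at megabase scale, small enough to keep the
packed representation cheap. A descriptive heterozygosity signature
(mass near half the modal depth relative to the peak) is reported but
not modelled; full mixture-model spectrum fitting is out of scope.

## Heterozygosity landscape statistics

Windows are fixed-width (default 50 kb), non-overlapping, tiled per
scaffold; a tail window shorter than half the width is dropped to avoid
rate inflation from tiny denominators, and window rates use callable
(non-N) bases. Genome-wide rates use callable bases as the denominator
for both SNPs and InDels, so the combined rate is their sum. Multi-allelic
records count as one heterozygous site. Per-gene heterozygosity divides
sites in the genomic gene span (first to last exon) by that span —
exonic- or CDS-restricted variants of the statistic would need a
stated denominator convention and are easy to derive from the same
counts. The top-divergent-region selector ranks windows by rate with
coordinate-order tie-breaking (deterministic), takes the top ceil(N·f),
and merges adjacent selections.

The full-sib inbreeding coefficient uses the classical recurrence
`F_t = (1 + 2F_{t-1} + F_{t-2})/4`, validated in the tests against a
vectorised gene-dropping Monte Carlo (identity-by-descent of two allele
draws through t generations of sib mating). Expected heterozygosity is
`H_0 (1 - F_t)`; the observed-vs-expected comparison is a plain Pearson
correlation, undefined (NaN, with a warning) when either vector is
constant.

## Variant annotation

Compartment precedence is exon > intron > intergenic over merged
intervals, half-open coordinates. Coding effects are evaluated on the
spliced CDS in coding-strand orientation: the reference allele is
checked against the assembly (mismatch is a hard error — it means VCF
and FASTA disagree), the affected codon is mutated and translated with
the standard genetic code; a new stop is `stop_gained`, an unchanged
amino acid `synonymous`, otherwise `nonsynonymous`. Exonic variants
outside CDS report `none` (UTR). InDel frame effects use the length of
the InDel that actually overlaps CDS, so boundary-spanning deletions
contribute only their overlapping bases to the mod-3 test. Ts/Tv counts
single-base substitutions only; multi-nucleotide records are excluded,
and zero transversions yields +inf with a warning rather than an error.
Percentage-of-genome figures are rounded to one decimal, matching the
convention of genome-report annotation tables.

## TE clustering, consensus and dating

**Alignment choices.** Divergence is measured on an affine-gap global
alignment (match +1, mismatch −2, gap open −6, extend −1) as mismatches
over aligned non-gap columns. Unit-cost edit distance is specifically
avoided here: it trades runs of mismatches for insertion–deletion pairs,
and with gap columns excluded from the metric that deflates measured
divergence by several percentage points at 20% true divergence. Affine
penalties keep substitution-only alignments gapless, making the
estimator unbiased in the regime the simulator produces. The metric is
the raw mismatch proportion by default; a multiple-hit corrected variant
(`kimura_divergence`, Jukes–Cantor form) is available but off by
default, since a raw "pair-wise comparison" is the conventional
repeat-landscape x-axis. Copies whose alignments are gap-heavy can be
flagged via `gap_fraction` rather than silently scored.

**Clustering.** Greedy centroid clustering, longest copy first (ties by
id, so fully deterministic): a copy joins the first group whose centroid
it matches at ≥ the identity threshold, else founds a group. This is
linear in copies × groups versus quadratic all-pairs clustering; on
well-separated families it yields the same partition, which the tests
check against a connected-components oracle. Because centroids are
member copies, a family at 20% internal divergence has copy-to-copy
identities near 0.65 and can shatter at nearby thresholds; an optional
refinement pass (used by the pipeline) merges groups whose consensuses
match and reassigns every copy to its best consensus, where the margin
is twice as large. The operation-level default threshold is 0.8; the
pipeline default is 0.6, sized so that one burst at 20% divergence
coheres while unrelated 300 bp families (chance identity ≈ 0.45) stay
apart. The number of groups a real TE census produces is data-dependent
and is not a target.

**Consensus.** Star alignment of members against the longest member;
per-column majority base with ties broken toward the reference base
(determinism); columns gapped in more than half the members are
dropped. Majority voting over ≥ tens of copies recovers the source
consensus essentially exactly at ≤ 20% divergence, and the tests bound
leave-one-out instability at ≤ 1% of columns.

**Peaks and dating.** The divergence distribution is summarised by a
Gaussian KDE (Scott bandwidth by default, overridable in divergence
units); peaks are local maxima with prominence ≥ 5% of the density
maximum, needing ≥ 50 values, with an all-equal sample short-circuiting
to its single value. A burst's age is `peak / substitution_rate`; the
substitution rate (subs/site/Myr) is a required user input for dating,
as divergence alone carries no clock. When a family is absent from a
sister lineage, `constrain_interval(origin_min, speciation)` brackets
the expansion between its minimum age and the speciation time.

## ERV screening

Hits carry query class (gag/pol/env/LTR/genome), identity and query
coverage in [0, 1]; the score is their product, the quantity whose
bimodality separates ancient from potentially active insertions.
Active-element filtering is strict (`>`) on both identity and coverage
at 0.8 — a hit at exactly 80% fails. Full proviruses are called per
scaffold and strand: LTR pairs within `max_span` (default 12 kb: a
gammaretroviral provirus is ~8–9 kb, plus slack) must enclose gag, pol
and env hits in strand-consistent genomic order; hits are consumed
leftmost-first so each participates in at most one full call, and
leftover component hits are reported as partials. Junction support
counts inward-facing read pairs with one mate inside the provirus span
and the other in the flank, insert within 3 s.d. of the library mean;
pairs with missing coordinates are skipped and tallied.

Production hit tables are expected from an external translated search in
BLAST outfmt-6-like form (with query lengths for coverage). The built-in
`search_hits` is a nucleotide-level helper for fixture-scale assemblies:
edit-distance infix alignment locates candidates fast, and each
candidate window is re-scored by an affine local alignment, whose
self-trimming yields honest identity and coverage (an unrelated window
scores a short chance segment with negligible coverage, where an
infix-forced alignment would report ~55–60% identity over the whole
query).

## Orthology and gene sets

Reciprocal best hits use a bit-score-like column; a tie for the top
score in either direction yields no pair (false orthologs are costlier
than missed ones) and tied genes are reported. Presence/absence against
a curated reference list distinguishes `present` (RBH), `hit_only` (no
RBH but some hit at ≥ 0.3 identity and coverage — too diverged to call,
not counted as loss), and `absent`; species-specific losses are genes
absent in exactly one species. Pseudogene disruption calls operate on
protein-to-genome alignments: an in-frame stop earlier than the final 5%
of the aligned protein (the tail exemption avoids flagging natural
stop-placement differences; configurable) or a genomic gap of length
≢ 0 mod 3. Whether a real pseudogene census requires one or both
disruption classes is a curation decision; both are reported separately
so either convention can be applied.

## Pipeline and problem sizes

The `report` pipeline simulates a bundle and runs every stage on it,
writing one JSON report whose every number is a direct re-export of a
library call with logged parameters; reruns with the same config and
seed are byte-identical. Default problem sizes in the tests and the
acceptance script are desk-scale by design — 50 Mb for rate recovery,
5 Mb for k-mer sizing, 2,000 copies for the divergence landscape,
hundreds of kb for pipeline smoke tests — sizes at which the binomial
and density tolerances in the tests are meaningful while a full run
stays in the minutes range on one core.

## Known limitations

- The simulator does not model linked selection, recombination maps, or
  demographic history; its purged/retained landscape is a convenient
  two-state caricature.
- TE copies decay by substitution only; real old copies are also
  truncated and internally deleted, which would widen divergence modes
  and stress the star-alignment consensus more than these tests do.
- The ERV helper search is nucleotide-level; diverged protein-coding
  homology (the regime where translated search shines) is out of its
  reach, which is why external hit tables are the production path.
- Genome-size estimation assumes a dominant single-copy coverage peak;
  highly repetitive or highly heterozygous genomes violate this and are
  reported descriptively at best.
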