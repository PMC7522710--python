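# Methods

## The biological model

An endogenous viral element (EVE) is a fragment of a viral genome integrated
into a host chromosome. When the integration site lies in a piRNA cluster,
the EVE is transcribed as part of a long single-stranded precursor and
processed into **primary piRNAs** (26–30 nt, uridine at position 1 — the 1U
bias). If a cognate virus replicates in the same cells, primary piRNAs
antisense to the viral RNA can guide its cleavage; the 3′ cleavage products
are processed into **secondary piRNAs** whose 5′ ends overlap the guiding
primary piRNA's 5′ end by exactly 10 nt and which consequently carry an
adenine at position 10 (the 10A bias, the base-pairing partner of the 1U).
This reciprocal cycle — ping-pong amplification — leaves two measurable
marks: complementary 1U/10A biases split by strand, and a sharp enrichment
of 10-nt 5′-overlaps between opposite-strand piRNAs.

The package measures both marks and, with its synthetic generator, verifies
that the whole chain (simulation → alignment → statistics) recovers the
parameters that were planted.

## Coordinate and strand conventions

All coordinates are 1-based inclusive. The 5′ end of a minus-strand
alignment is the **rightmost** base of its footprint in plus coordinates.
This convention is load-bearing: the overlap statistic pairs a plus read
with 5′ end i against a minus read with 5′ end j at distance d = j − i + 1,
so an exact ping-pong pair (10-nt overlap) satisfies i = j − 9. Tests assert
the convention at the aligner, coverage and orientation-mapping layers.

## Synthetic-data generator

The generator emulates the read populations of an EVE-carrying, virus-
infected insect library:

- **Virus**: i.i.d. random sequence, default 10,700 nt at GC 0.5 — the size
  class of an insect-specific flavivirus genome.
- **EVE**: 4 viral fragments (default 300–2,000 nt each), two of them
  reverse-complemented, diverged by i.i.d. substitutions at rate 0.04,
  concatenated without spacers and embedded between 5,000-nt random host
  flanks. Adjacent placement mirrors the mosaic structure of naturally
  observed EVEs; realized identity is recorded per fragment from the planted
  substitution count, so "identity ≈ 96%" is an exact bookkeeping fact, not
  an estimate.
- **siRNAs**: 21 nt, uniform over the virus, both strands equiprobable —
  the hallmark of active infection.
- **Primary piRNAs**: 26–30 nt, drawn from the EVE region of the contig in
  transcript orientation, so fragments flipped relative to the virus yield
  reads antisense to the virus. `u1_enforcement` (default 0.9) is the exact
  1U fraction: with that probability the 5′ start is drawn among template
  positions reading U, otherwise among non-U positions. Start selection by
  rejection over template positions (never by mutating the read) keeps reads
  perfect substrings of their template.
- **Secondary piRNAs**: for a sampled antisense primary with virus-coordinate
  5′ end j, a plus-strand read is drawn **from the virus sequence** with 5′
  end at j − 9 (exact 10-nt overlap). Partner primaries are sampled among
  U-starting antisense primaries, reflecting the preferential loading of 1U
  piRNAs onto PIWI proteins; with 4% EVE–virus divergence this yields a
  secondary 10A fraction of ≈ 0.96 (1 − divergence, with a small Bayes
  correction for substitutions that created the U). The primary template is
  the EVE and the secondary template is the virus — that asymmetry is the
  model and is deliberately not configurable.
- **Background** (`n_background`, default 0): piRNA-sized reads uniform over
  both viral strands with no positional coupling — a ping-pong-free
  degradation population used to emulate EVE-knockout libraries, which still
  contain piRNA-sized viral fragments but no amplification structure.
- Per-base substitution sequencing error (default 0.001), constant Phred 40
  qualities (a `degrade_tail` option writes low-quality tails for trimmer
  tests), and 19–33 nt size selection with rejected reads counted.

What the generator does **not** emulate: ligation/PCR bias, indel errors,
quality-dependent error profiles, piRNA phasing, flank-derived piRNAs
(reads from host sequence flanking the EVE), or multiple EVE loci. Passing
tests therefore demonstrate correctness of the analysis logic under the
stated stochastic model, not robustness to every artefact of real libraries.

## Trimming

3′-adapter trimming: the leftmost position where the adapter prefix matches
the read suffix with ≤10% mismatches over ≥3 overlap columns, iterated to a
fixpoint so that trimming is idempotent (a cut can expose a new short
adapter-like suffix; iterating removes it). The quality rule is mean Phred
strictly greater than the threshold (default 20); aggregation by mean is a
declared choice, configurable. Reads without an adapter are discarded by
default (`require_adapter=False` passes them through untrimmed). Note the
adapter is at the read's 3′ end, as dictated by small-RNA 3′-linker library
chemistry.

## Aligner

Ungapped (small RNAs vs small references; indels are vanishingly rare in
this regime), both strands, mismatch strata 0/1: if any 0-mismatch placement
exists, 1-mismatch placements are suppressed. Candidates come from the first
and last k-mers of the query; with k ≤ floor(readlen/2) the two seed windows
are disjoint and a single mismatch cannot evade both, so the search is
exhaustive — `align_reads` caps k at half the shortest read. Equally-best
placements are all reported, ordered by (position, strand with + first), and
down-weighted by 1/n_best; fractional weighting is deterministic and
seed-free, unlike single-random-hit reporting. An independent brute-force
scanner over every offset and strand serves as the oracle in tests.

## EVE discovery

Exact 11-mer seeds between contig and virus (both virus orientations) are
extended ungapped under X-drop (match +1, mismatch −2, drop 20), truncated
to the maximal-scoring extent, deduplicated per diagonal, and kept above
score 30 — at that threshold random hits between a ~10 kb virus and a ~20 kb
contig are improbable. Same-orientation HSPs on the same diagonal with gaps
≤ 50 nt are chained into fragments. Identity uses aligned columns as the
denominator; when the sequences are available at chaining time the matches
are recounted column-by-column over the merged interval, which makes the
reported percent identity exactly reproducible from the two sequences (the
pooled-HSP count with gap columns as mismatches is the fallback when only
HSPs are given). Ungapped extension is appropriate here because the planted
divergence model has no indels; real EVEs with indels would fragment into
multiple chained HSPs instead.

## Signature statistics

- Logo matrices use the read sequences as read (5′→3′, truncated to 20 nt,
  reported as RNA), not the reference, so sequencing errors and EVE/virus
  divergence show through. Information content is I(p) = 2 + Σ f log₂ f with
  0·log 0 ≡ 0 and no small-sample correction.
- The overlap spectrum is computed on 5′ ends only (read lengths ignored)
  over d = 1..30; the z-score of each bin is taken against the mean and
  population SD of all 30 bins, the bin itself included — the convention of
  the signature tools used in the field. Both choices are configurable.
  z is invariant to rescaling, so counts and probabilities give identical
  z-scores (asserted by test). A spectrum with a single nonzero bin has
  z = √29 ≈ 5.385 at that bin — the theoretical ceiling at Dmax = 30 — which
  the tests check to machine precision.
- Region-restricted spectra attribute a pair to the region by the + strand
  read's 5′ position (a deterministic tie-break; region additivity then
  holds exactly and is asserted).
- EVE-locus alignments are re-expressed in virus coordinates through the
  fragment table; strand flips for reverse-orientation fragments. Alignments
  not fully contained in a fragment are dropped and counted.

## Disambiguation

"Unambiguous" is operationalized as presence/absence of 0-mismatch hits on
each reference: virus_only / eve_only / shared / unmapped partition every
read. Sequencing errors push true reads to unmapped rather than to a wrong
class — conservative by construction. The diagnostic-site density (fraction
of EVE columns differing from the virus) is reported alongside, since it
bounds the power of the classification: at zero divergence everything is
shared, which the tests assert.

## Prevalence

Carrier prevalence is positive/tested as a percentage with a Wilson score
interval (via statsmodels). For 28 positive of 31 tested this gives 90.3%
(75.1%–96.7%); other interval methods (e.g. Clopper–Pearson) differ by a
point or two at this n, which is why the method is named in the output.

## Problem sizes and numerical choices

Test and validation workloads are sized for a laptop-class single core:
parameter recovery uses 20,000 primary + 20,000 secondary reads (binomial
SE of the recovered 1U fraction ≈ 0.002); the ablation contrast uses 20
seed-replicates of 1,500+1,500 reads against 3,000 background reads; aligner
oracle equivalence uses 10,000 reads vs a 20 kb reference. All randomness
flows from a single integer seed through `numpy.random.default_rng`; a fixed
seed reproduces every output byte-for-byte, which the pipeline test asserts
on two complete runs.

## Known limitations

- The aligner targets references up to ~1 Mb; no FM-index, no genome scale.
- No probabilistic reassignment of shared reads (no EM multi-mapper model).
- The percent-identity definition (ungapped columns, chaining gaps counted
  when sequences are absent) is one of several defensible conventions;
  comparisons with gapped-alignment identities can differ slightly.
- Simulated knockout libraries model the *absence* of ping-pong as uniform
  background; real knockout tissues may retain residual structured piRNAs
  from other loci.
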