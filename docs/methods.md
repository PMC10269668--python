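# Methods

This note documents the model, its tunable parameters, the numerical choices made
where the design was genuinely open, what the synthetic data emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Classification model

Each input sequence is summarised by a fixed-order 26-feature vector and scored by a
random forest; the plasmid call is the fraction of trees voting plasmid compared
against a probability threshold (default 0.5). Random forests are insensitive to
feature scaling, so no normalisation is applied anywhere.

Two routing rules precede the model. Sequences longer than `length_cutoff`
(default 500 kb) are labelled chromosome without feature extraction: molecules that
long essentially never assemble from plasmids, and the bypass removes most of the
cost of scoring finished genomes. Sequences shorter than `min_length`
(default 500 bp, configurable down to 1) are reported as `filtered` — a distinct
output state rather than a silent drop, so record counts always reconcile.

## Shared-k-mer features

K-mers are canonical (the lexicographic minimum of a k-mer and its reverse
complement), which makes every downstream quantity strand-invariant; windows
containing a non-ACGT symbol are skipped, and soft-masked lowercase bases are
uppercased rather than skipped. Internally a k-mer is packed into a 64-bit integer
(2 bits per base, A<C<G<T, big-endian), an encoding that preserves lexicographic
order and limits k to 31 — comfortably above the defaults of 18 (chromosome side)
and 25 (plasmid side).

The min-hash sketch keeps a k-mer iff `H(kmer) < f * 2**64`, where `H` is a
splitmix64 finalizer applied to the packed code XORed with a mixed fixed seed (42).
The hash is seedless in effect — the seed is a constant stored in the database
header — so databases are deterministic across runs and platforms, which is the
property the sketch actually needs; no cryptographic strength is required.
The chromosome-side database uses `f = 0.1`; the plasmid-side databases are built
unsketched. Subtraction databases are computed set-theoretically *after* sketching,
on a common k per side, with the subtrahend unsketched so every shared k-mer is
removed; the result inherits the minuend's sketch fraction.

`shared_fraction` filters the query's distinct canonical k-mers by the *database's*
sketch criterion before counting, and divides by the query's sketch-surviving k-mer
count (not the database size). This query-relative normalisation makes a verbatim
sample of a database's source score exactly 1.0 regardless of sketching, and keeps
the fraction in [0, 1]. Fractions are expressed on [0, 1] rather than percent; the
`rp` ratio is scale-invariant either way. `rp(0, 0)` is defined as 0.5 (neutral):
a sequence sharing nothing with either class should not be biased by the degenerate
arithmetic.

## Marker features

The −log(E-value) scale is base 10: the presence threshold of 50 then corresponds to
E ≤ 1e-50, consistent with conventional E-value reporting. The transform is floored
at 0 (E ≥ 1) and capped at 300 (E underflowed to 0). All threshold comparisons are
inclusive exactly as specified: presence at −log₁₀E ≥ 50, RDS bias +1 at mean
RDS ≥ 5 and −1 at mean RDS ≤ −10. Categories with no hits contribute 0 to every
feature; 0 is an explicit absence encoding, below any attainable positive score.
`maxEvalue` is the maximum of the five plasmid-indicating E-value features
(conjugation, mobilization, AMR, replication, oriT) and deliberately excludes
`rRNAMaxEvalue`, which indicates chromosomes.

### The built-in search backend

Marker search is abstracted behind a backend contract (deterministic hit lists with
a common schema). The built-in backend is a self-contained aligner:

- **ORFs**: a six-frame ATG→stop scan reporting, for each stop codon, the maximal
  ORF (earliest in-frame ATG after the previous stop) of at least 30 codons.
  ORFs without a terminating stop, or interrupted by an ambiguous codon, are not
  reported. This is far cruder than a gene finder but strand-symmetric and exact on
  planted genes.
- **Scoring**: best ungapped local alignment — the maximum over all diagonals of the
  maximum-sum contiguous run — under BLOSUM62 for proteins and +5/−4 for
  nucleotides. Nucleotide motifs (oriT, rRNA) are scored on both strands and the
  maximum taken. The +5/−4 pair was chosen so that an exact copy of the 60-bp oriT
  motif scores 300 and clears the 1e-50 presence threshold under the pseudo E-value
  below.
- **Statistics**: a raw score `S` becomes the pseudo E-value `e = m·n·2^(−S)`
  (`m`, `n` the query and target lengths). This is *not* a calibrated
  Karlin–Altschul statistic; it is a deterministic, monotone stand-in adequate for
  exact or near-exact planted markers, and it is documented as such wherever it
  surfaces.

### RDS aggregation

Per ORF, only the best MPS hit (lowest E-value; ties broken by higher score, then
marker id) is kept, and an ORF enters the RDS average only if that best hit reaches
E ≤ 1e-10. Under the steep pseudo E-value the best random ORF-vs-marker score sits
orders of magnitude above this cutoff, so the average reflects confidently matched
genes rather than alignment noise. Sequences with no qualifying ORFs report
(0, 0, 0).

## Training procedure

Replicons are cut into ten window strata — (window, overlap) from (500 kb, 50 kb)
down to (500 bp, 50 bp) — with 0-based half-open windows on an arithmetic grid;
trailing fragments shorter than the window are dropped so every example in a stratum
has exactly the stratum's length. Chromosomal replicons whose source molecule is
shorter than 500 kb are excluded entirely (plasmid sequences mislabelled as
chromosome are the main contamination risk in that length range). Within each
stratum `floor(0.8 · N)` windows are drawn uniformly without replacement and the
draw is then truncated to a 100,000-window ceiling ("sample then truncate"); the 80%
draw is over windows, not source replicons. No class balancing is applied at
training time; the per-class counts are recorded in the model's training summary.

The forest (500 trees) is fitted on a random 2/3 of the sampled windows and
evaluated on the remaining 1/3. All randomness flows from one explicit integer seed;
repeated training derives per-repetition seeds from a `SeedSequence` so that one
repetition reproduces a single `train` call exactly. Feature importance is the
forest's impurity-decrease importance (non-negative, summing to 1).

## Benchmark harness

Metrics with a zero denominator are reported as missing (`None`), never coerced to
0 or 1, and prevalence is always reported alongside because precision, F1 and
accuracy are functions of class balance. AUC is the Mann–Whitney rank-sum estimator
with ties counted 0.5, checked in the tests against brute-force pair counting and
scikit-learn. Balanced down-sampling equalises the class counts within each exact
length stratum, uniformly without replacement under a seed; already-balanced strata
pass through unchanged.

Truth labelling of assembled contigs uses k = 21 (the midpoint of the two feature
k values; configurable). A contig sharing < 95% of its k-mers with the joint
reference is discarded as mis-assembled; the rest are labelled by the larger of the
shared fractions against the chromosome set versus the plasmid set, compared
jointly, with exact ties discarded as ambiguous.

## Synthetic data

The generator's defaults define the study conditions used throughout the tests:
a 600-kb chromosome (long enough to survive the 500-kb training filter), eight
plasmids of 5–60 kb, and order-2 Markov backbones at GC 0.42 (chromosome) versus
0.58 (plasmid) with a mild context-persistence term. The GC separation is a
deliberately strong stand-in for the taxonomic k-mer signal of real replicon
collections; the separation margin is asserted empirically at fixed seed in the
tests, never assumed.

Marker cassettes are planted as exact copies of toy database entries: each plasmid
receives one conjugation, mobilization, replication and AMR gene, two positive-RDS
marker-protein genes and the oriT motif; the chromosome receives rRNA motifs and
negative-RDS marker-protein genes. Protein cassettes are reverse-translated with
randomly chosen synonymous codons and terminated with TAA, so the planted ORF
translates exactly to its database protein and the naive backend recovers it with a
pseudo E-value far below 1e-50. The manifest records every replicon label and
cassette coordinate; everything is a pure function of the seed.

The fragmenter draws contig lengths from a log-normal (median 2 kb, σ = 0.7,
floor 200 bp) and cuts verbatim subsequences — no read errors, chimeras, coverage
model or repeat-induced misassembly. Consequently, passing the end-to-end tests
demonstrates that the pipeline's machinery is correct and internally consistent
(features separate the classes they were built to separate, training recovers the
planted signal, labels are strand-invariant and deterministic); it does not
demonstrate field performance on real assemblies, where inter-replicon similarity,
shared mobile elements and assembly artefacts make the problem materially harder.

## Problem sizes

The default end-to-end check trains on the window strata from 500 bp to 10 kb of the
default synthetic genome set (about 2,900 sampled windows covering ~3.8 Mb) with
ntrees = 500, and labels 300 fragmented contigs; these sizes were chosen as the
smallest at which every stratum is well populated and both classes appear in every
stratum. Larger window sizes (20 kb–500 kb) are exercised structurally by the
windowing tests; on a single 600-kb chromosome they would contribute too few windows
per stratum to be informative as training strata.

## Known limitations

- The pseudo E-value is not comparable across backends; a model trained with the
  built-in backend must be used with the built-in backend. Adapters shelling out to
  external aligners (HMMER, DIAMOND, BLASTN) would satisfy the same hit schema but
  are not included.
- The ORF scanner has no model of alternative start codons, overlapping genes or
  frameshifts.
- k is capped at 31 by the 2-bit packing; the defaults (18/25) and the labelling k
  (21) are well inside the cap.
- Marker databases and k-mer databases are held in memory; the design targets
  reference sets up to the low hundreds of megabases, not metagenomic corpora.
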