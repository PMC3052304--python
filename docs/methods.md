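# Methods

## Screening model

`readscrub` treats decontamination as a per-read binary decision backed
by local alignment. A read is compared against *remove* databases
(references whose matches mark it as contamination) and, if it looks
like contamination, against *retain* databases (references for wanted
organisms). The decision statistic is the pair (query coverage,
alignment identity) of the best local alignment per role:

- coverage = 100·(M+R+I)/query_length — the fraction of read bases
  inside the alignment;
- identity = 100·M/(M+R+I+D) — the fraction of alignment columns that
  are exact base matches.

Both are floored to integers before comparison with the user thresholds
(so a 100% threshold is satisfiable by perfect matches, and 99.95%
counts as 99%). Labels: *contamination* iff the remove hit passes both
thresholds and the retain hit does not; *both* iff both pass; *clean*
otherwise — including reads whose only passing hit is against a retain
database, because only the remove databases define contamination.
"Both" reads are retained by default (`--remove-both` flips this).

The identity denominator is a genuine design choice: with indels one
can normalize by query span, reference span, or all alignment columns.
We use all columns (M+R+I+D), the most conservative reading (every
indel column dilutes identity), and isolate it in
`align.compute_coverage_identity` with unit tests pinning the
convention. Similarly, the "more similar" ordering used to color
hit-to-both pairs in the plot data is the coverage+identity sum, with
ties awarded to the retain side (conservative: the read is kept).

## Alignment engine

The engine is an FM-index seed-and-extend local aligner:

- **Index.** Reference sequences are split at runs of ≥ 200 Ns,
  deduplicated, filtered for > 5% ambiguous bases, packed into chunks
  (default 10 Mbp of sequence per chunk; chunks are searched jointly and
  results joined), and indexed: suffix array by vectorized prefix
  doubling (an O(n log n) sort), BWT with one unique sentinel per
  sequence (matches can never span sequences), full occurrence table
  over A/C/G/T, suffix array sampled at stride 32. Remaining ambiguity
  codes are replaced by a seeded-random base drawn uniformly from the
  code's candidate set and recorded in an ambiguity mask.
- **Seeding.** Every k-mer of the read and of its reverse complement
  (k = 12) is searched exactly by backward search; k-mers containing N
  or occurring more than 500 times are skipped. Occurrences are grouped
  by (sequence, strand, diagonal), clusters whose diagonals differ by
  more than half the band width are kept apart, and at most 8 clusters
  (largest seed count first) are extended per read and strand.
- **Extension.** Banded affine-gap Smith–Waterman around the cluster
  diagonal (band ±50, widened by the cluster's diagonal spread), scoring
  match +1, mismatch −3, gap of length L −(5 + 2L), minimum reported
  score 30. A column is M only if the bases are equal, the query base is
  a concrete A/C/G/T, and the reference position is not masked — an N in
  the query is forced to mismatch, and a randomized reference
  replacement can never produce a match. The DP fill is a numba kernel;
  traceback prefers diagonal, then insertion, then deletion at ties.
- **Reporting.** Candidates from all chunks are merged, overlapping
  candidates deduplicated, the top Z (default 1) by score kept, and ties
  broken by higher identity, then lexicographically smaller reference
  id, then smaller reference coordinate — output is deterministic by
  construction; no stage of alignment consumes randomness.

Local alignment may clip read ends (clipped bases reduce coverage; no
clip operators appear in the extended CIGAR). Hits serialize to a
4-column TSV (query id, reference id, coverage, identity, two decimals)
or minimal SAM with '='/'X' operators; the SAM reader rejects plain 'M'
as ambiguous.

Correctness is anchored to two independent oracles in the test suite:
FM-index occurrence sets are compared against linear-scan string search
(texts up to 50 kbp), and engine best scores against an unbanded
full-DP local alignment on homologous instances up to 200×2000 bp with
a guaranteed seed.

## Synthetic data

The simulator emulates the study conditions the package is evaluated
under, not any particular instrument:

- **Genomes** are seeded i.i.d. base draws at a chosen GC content
  (default 0.5), optionally with planted N runs and duplicated segments
  to exercise N-splitting and repeat behavior.
- **Metagenome reads**: sources drawn with probability proportional to
  genome length, uniform start and strand; lengths normal(380, 100)
  rounded and redrawn while < 100 bp or longer than the source; errors
  as independent per-base events — substitution 0.85% (to a uniformly
  chosen different base), indel 0.15% (1 bp, insertion or deletion
  equally likely), substitutions applied before indels; uniqueness and
  N-freedom enforced by rejection resampling. Recorded per-read
  substitution/insertion/deletion counts refer to this edit script.
- **Tiled reads** for sensitivity benchmarks: fixed-length windows (200,
  500 or 1000 bp) starting at multiples of read_len·(1−overlap),
  full-length windows only, N-containing windows discarded, forward
  strand only (the aligner handles strand regardless).
- **Exact-error injection** for worst-case experiments: E = round(rate ×
  length) errors at distinct uniform positions, round(0.15·E) of them
  1-bp indels (half-up rounding so per-read counts are reproducible
  integers), the rest substitutions.

What the synthetic data does **not** model: repeat structure and low
complexity regions of real genomes (the dominant cause of unalignable
reads in practice), homopolymer-biased indel profiles, quality values,
community abundance structure, and inter-genome homology (the remove
and retain genomes are independent draws, so the hit-to-both class is
essentially empty on synthetic data). Passing benchmarks here therefore
demonstrate the correctness of the machinery under the stated error
model, not classification performance on real host/microbe mixtures,
where shared or repetitive sequence makes both the error modes and the
both-class materially larger.

## Benchmark experiments (`readscrub.experiments`)

- **Accuracy**: a 2 Mbp remove genome and two 1 Mbp retain genomes,
  10,000 simulated reads per role at the default error model, screened
  at 95/94 thresholds; accuracy = 100·(TP+TN)/N with both-hits counted
  FN for contaminants and TN otherwise (the "both" read is retained, so
  for a true contaminant that is a miss). These problem sizes were
  chosen as the package's desk-scale default; at 20,000 reads the
  experiment resolves accuracies to 0.005%.
- **Sensitivity**: a 1 Mbp genome tiled into 500 bp reads at 50%
  overlap (3,999 reads), aligned back with default parameters and no
  thresholds; sensitivity = 100·aligned/total.

`scripts/acceptance.py --seed S --out F` recomputes both, plus the
threshold-rounding example, end to end from the given seed.

## Numerical and degenerate-input choices

- Percentages are exact IEEE doubles of integer ratios; flooring uses
  `math.floor` directly (ratios of desk-scale integers cannot land
  within double rounding error below an integer).
- Duplicate filtering is case-insensitive full-string equality
  (sequences are upper-cased on read); no reverse-complement or prefix
  collapsing.
- Reference chunking is sequential next-fit in input order; a sequence
  larger than the chunk capacity gets its own chunk, never split.
- Empty input files parse as zero records; validation reports them as
  invalid ("no records"); an empty classification run writes valid
  empty output files plus a warning.
- The confusion-matrix treatment of "Hit to both" is switchable
  (`both_as_positive`) because the opposite reading (both = a positive
  contamination call) is defensible when both-reads are being removed.
- Worker parallelism only partitions the read stream (fork-based);
  per-read alignment is deterministic and seed-free, so worker count
  never changes results.

## Known limitations

- The FM-index uses a plain (uncompressed) occurrence table — about 32
  bytes per reference base in memory; appropriate for the desk-scale
  databases this package targets, not for multi-Gbp genomes.
- The banded extension assumes the true alignment stays within ±band of
  the seed diagonal; alignments with net indel drift beyond 50 bp are
  not recovered (configurable via `--band`).
- The engine finds one best hit per role; secondary hits are internal
  only (`z` > 1 widens the candidate pool but still reports one hit).
- No paired-end awareness, quality-based trimming, or SFF/BAM input.
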