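# readscrub

Identification and removal of contaminant reads from genomic and
metagenomic long-read datasets.

Sequences obtained from impure samples or nucleic acid preparations
routinely contain DNA from sources other than the intended sample — most
prominently host (e.g. human) DNA in microbial and viral metagenomes.
Left in place, such contamination corrupts assemblies and downstream
conclusions, and for human-associated samples it must be removed before
data can be published. `readscrub` screens longer reads (hundreds of bp
and up) against one or more **remove** databases (genomes whose matches
mark a read as contamination) and optional **retain** databases (genomes
whose matches rescue look-alike reads), and partitions the input into
*clean*, *contamination*, and *hit-to-both* sets.

## Method

Each read is locally aligned against FM-indexed reference chunks with a
seed-and-extend engine: exact k-mer seeds (default k = 12, both strands)
are found by backward search on the Burrows–Wheeler transform, clustered
by diagonal, and extended with a banded affine-gap Smith–Waterman
alignment (match +1, mismatch −3, gap open −5, gap extend −2, minimum
score 30). Alignments carry an extended CIGAR that distinguishes matches
(`M`) from replacements (`R`), so the two screening statistics need no
realignment:

```
query coverage     c = 100 · (M + R + I) / |read|
alignment identity p = 100 · M / (M + R + I + D)
```

A read is called **contamination** when ⌊c⌋ ≥ C and ⌊p⌋ ≥ P against any
remove database (default thresholds C = 95, P = 94; values are floored,
so 99.95% counts as 99%), and **hit-to-both** when a retain database hit
also passes — those reads are kept by default. An `N` in a read is
forced to mismatch, and reference ambiguity codes (randomly concretized
at indexing time, after splitting reference sequences at runs of ≥ 200
Ns) are masked so they can never manufacture identity.

The package also ships the evaluation machinery: a seeded synthetic
genome and read simulator (per-base substitution/indel error model,
exact-error injection, fixed-overlap tiling) with construction-time
ground truth, and sensitivity / confusion-matrix / accuracy scoring.

## Worked example

```python
import readscrub as rs

host = rs.make_synthetic_genome(500_000, seed=10, id="host_chr1")
microbe = rs.make_synthetic_genome(200_000, seed=20, id="microbe_chr1")
rs.write_sequences([host], "host.fasta")
rs.write_sequences([microbe], "microbe.fasta")
reads = (rs.simulate_reads([(host, "remove")], 300, seed=30, id_prefix="h")
         + rs.simulate_reads([(microbe, "retain")], 700, seed=31,
                             id_prefix="m"))
rs.write_sequences([r.record for r in reads], "metagenome.fasta")
```

```
$ readscrub makedb -i host.fasta -out hostdb --seed 0
indexed 1 sequences into 1 chunk(s) at hostdb
$ readscrub run -i metagenome.fasta -dbs hostdb -dbs_retain microbe.fasta \
      -c 95 -i_pct 94 -out screened --seed 1
clean=700	contamination=300	both=0	percent_contamination=30.0000
```

All 300 reads simulated from the host genome (with the default 0.85%
substitution + 0.15% indel error model) are flagged as contamination;
all 700 microbial reads stay clean. `screened_clean.fasta`,
`screened_contamination.fasta` and `screened_both.fasta` partition the
input; `screened_remove_hits.tsv` holds the lightweight per-read hit
table (query id, reference id, coverage, identity):

```
h000000	host_chr1	99.12	99.78
h000001	host_chr1	100.00	99.62
```

`screened_plotdata.txt` contains the binned coverage-vs-identity counts
(with column/row marginal sums) behind the threshold-selection dot
plots. The same workflow is available as library calls
(`rs.build_database`, `rs.screen_reads`, `rs.run_pipeline`), and
`readscrub simulate / tile / align / classify / evaluate / plotdata`
expose the individual stages.

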