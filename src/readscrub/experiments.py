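"""Benchmark experiments on synthetic data.

Scaled-down analogs of the classic evaluation of alignment-based
decontamination: a classification-accuracy experiment on simulated
metagenomes (contaminant reads drawn from a "remove" genome, wanted
reads from independent "retain" genomes, 0.85% substitution / 0.15%
indel error model, normal(380, 100) read lengths) and an alignment
sensitivity experiment on error-free reads tiled across a genome at 50%
overlap.  Problem sizes default to desk scale: a 2 Mbp remove genome,
two 1 Mbp retain genomes and 10,000 reads per role for accuracy; a
1 Mbp genome tiled into 500 bp reads for sensitivity.
"""

from __future__ import annotations

from typing import Optional

from .align import AlignerParams, align_read
from .classify import Thresholds
from .evaluate import accuracy, confusion, sensitivity
from .pipeline import screen_reads
from .refdb import build_database
from .simulate import make_synthetic_genome, simulate_reads, tile_reads


def accuracy_experiment(seed: int,
                        n_reads_per_role: int = 10_000,
                        remove_bp: int = 2_000_000,
                        retain_bp: int = 1_000_000,
                        thresholds: Optional[Thresholds] = None,
                        params: Optional[AlignerParams] = None) -> dict:
    """Full-pipeline classification accuracy on a simulated metagenome.

    Returns a dict with the confusion matrix, accuracy (percent) and the
    problem size.  Both-hits score as FN (contaminant) / TN otherwise.
    """
    thresholds = thresholds or Thresholds(95, 94)
    params = params or AlignerParams()
    base = int(seed) % (2 ** 20)
    remove_g = make_synthetic_genome(remove_bp, seed=base * 10 + 1, id="removeG")
    retain_a = make_synthetic_genome(retain_bp, seed=base * 10 + 2, id="retainA")
    retain_b = make_synthetic_genome(retain_bp, seed=base * 10 + 3, id="retainB")
    remove_idx = build_database([remove_g], role="remove", seed=base * 10 + 4)
    retain_idx = build_database([retain_a, retain_b], role="retain",
                                seed=base * 10 + 5)
    contam = simulate_reads([(remove_g, "remove")], n_reads_per_role,
                            seed=base * 10 + 6, id_prefix="con")
    wanted = simulate_reads([(retain_a, "retain"), (retain_b, "retain")],
                            n_reads_per_role, seed=base * 10 + 7,
                            id_prefix="mic")
    reads = contam + wanted
    classifications, _, _ = screen_reads(
        [r.record for r in reads], remove_idx, retain_idx, thresholds, params)
    truth = {r.record.id: r.label for r in reads}
    cm = confusion(classifications, truth)
    return {"accuracy": accuracy(cm), "tp": cm.tp, "fp": cm.fp,
            "tn": cm.tn, "fn": cm.fn, "n_reads": cm.n}


def sensitivity_experiment(seed: int,
                           genome_bp: int = 1_000_000,
                           read_len: int = 500,
                           overlap: float = 0.5,
                           params: Optional[AlignerParams] = None) -> dict:
    """Fraction of error-free tiled reads the aligner maps back to their
    source genome, with no coverage/identity thresholds applied."""
    params = params or AlignerParams()
    base = int(seed) % (2 ** 20)
    genome = make_synthetic_genome(genome_bp, seed=base * 10 + 8, id="refG")
    indexes = build_database([genome], role="remove", seed=base * 10 + 9)
    tiles = tile_reads(genome, read_len, overlap)
    aligned = [align_read(t.record, indexes, params) is not None
               for t in tiles]
    return {"sensitivity": sensitivity(aligned), "n_reads": len(tiles)}
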