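"""End-to-end screening workflow.

read -> validate -> (optional prefilter) -> align against "remove"
databases -> align passing reads against "retain" databases -> classify
into clean / contamination / both -> split output files, plot data and a
summary report.  Retain alignment is only performed for reads whose
remove hit passes the thresholds (possible contaminants), unless
``retain_all`` asks for full plot data.

Deterministic for a fixed seed and any worker count: workers only chunk
the read stream, per-read alignment is seedless and order is restored.
"""

from __future__ import annotations

import multiprocessing as mp
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import seqio
from .align import AlignerParams, AlignmentHit, align_read, write_hits_tsv
from .classify import (PlotData, ReadClassification, Thresholds,
                       build_plot_data, classify_reads, split_output)
from .refdb import FMIndex, build_database
from .seqio import FilterStats, SequenceRecord


class ValidationError(ValueError):
    """Input failed DNA validation; further processing is restricted."""


@dataclass
class RunConfig:
    inputs: list[Union[str, Path]] = field(default_factory=list)
    remove_dbs: list[Union[str, Path]] = field(default_factory=list)
    retain_dbs: list[Union[str, Path]] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)
    params: AlignerParams = field(default_factory=AlignerParams)
    out_prefix: str = "readscrub_out"
    out_format: Optional[str] = None   # None: fastq if input has quals
    gzip: bool = False
    seed: int = 1
    workers: int = 1
    retain_both: bool = True           # "both" reads kept, not removed
    retain_all: bool = False           # align every read to retain DBs
    prefilter: bool = False
    db_seed: int = 0
    max_bases_per_chunk: int = 10_000_000

    def validate(self) -> None:
        if not self.inputs:
            raise ValueError("at least one input file is required")
        if not self.remove_dbs:
            raise ValueError('at least one "remove" database is required')


# ---------------------------------------------------------------------------
# alignment driver (optionally process-parallel)

_worker_state: dict = {}


def _init_worker(indexes, params):
    _worker_state["indexes"] = indexes
    _worker_state["params"] = params


def _align_chunk(chunk: list[SequenceRecord]) -> list[Optional[AlignmentHit]]:
    indexes = _worker_state["indexes"]
    params = _worker_state["params"]
    return [align_read(rec, indexes, params) for rec in chunk]


def align_all(records: Sequence[SequenceRecord],
              indexes: Sequence[FMIndex],
              params: AlignerParams,
              workers: int = 1) -> dict[str, AlignmentHit]:
    """Best hit per read id (reads without a hit are absent)."""
    if workers <= 1 or len(records) < 200:
        hits = [align_read(rec, indexes, params) for rec in records]
    else:
        chunks = [list(records[i::workers]) for i in range(workers)]
        ctx = mp.get_context("fork")
        with ctx.Pool(workers, initializer=_init_worker,
                      initargs=(indexes, params)) as pool:
            results = pool.map(_align_chunk, chunks)
        hits_by_id = {}
        for chunk, chunk_hits in zip(chunks, results):
            for rec, hit in zip(chunk, chunk_hits):
                hits_by_id[rec.id] = hit
        hits = [hits_by_id[rec.id] for rec in records]
    return {rec.id: hit for rec, hit in zip(records, hits) if hit is not None}


def screen_reads(records: Sequence[SequenceRecord],
                 remove_indexes: Sequence[FMIndex],
                 retain_indexes: Sequence[FMIndex] = (),
                 thresholds: Optional[Thresholds] = None,
                 params: Optional[AlignerParams] = None,
                 retain_all: bool = False,
                 workers: int = 1,
                 ) -> tuple[list[ReadClassification],
                            dict[str, AlignmentHit], dict[str, AlignmentHit]]:
    """Align and classify an in-memory read set.

    Returns (classifications in input order, remove hits, retain hits).
    """
    thresholds = thresholds or Thresholds()
    params = params or AlignerParams()
    remove_hits = align_all(records, remove_indexes, params, workers)
    if retain_indexes:
        from .classify import passes_thresholds
        if retain_all:
            candidates = list(records)
        else:
            candidates = [r for r in records
                          if r.id in remove_hits
                          and passes_thresholds(remove_hits[r.id], thresholds)]
        retain_hits = align_all(candidates, retain_indexes, params, workers)
    else:
        retain_hits = {}
    classifications = classify_reads(remove_hits, retain_hits, thresholds,
                                     read_ids=[r.id for r in records])
    return classifications, remove_hits, retain_hits


# ---------------------------------------------------------------------------
# full pipeline over files

def _load_databases(paths: Sequence[Union[str, Path]], role: str,
                    config: RunConfig) -> list[FMIndex]:
    """Each path is either a serialized index directory or a FASTA file."""
    indexes: list[FMIndex] = []
    for path in paths:
        p = Path(path)
        if p.is_dir():
            manifest = p / "manifest.json"
            if manifest.exists():
                indexes.append(FMIndex.load(p))
            else:  # a directory of chunk subdirectories
                for sub in sorted(p.iterdir()):
                    if (sub / "manifest.json").exists():
                        indexes.append(FMIndex.load(sub))
        else:
            indexes.extend(build_database(
                seqio.read_sequences(p), role=role, seed=config.db_seed,
                max_bases_per_chunk=config.max_bases_per_chunk))
    return indexes


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the summary dictionary.

    Raises :class:`ValidationError` when the input fails DNA validation.
    """
    config.validate()
    records: list[SequenceRecord] = []
    for path in config.inputs:
        records.extend(seqio.read_sequences(path))
    report = seqio.validate_dna(records)
    if not report.ok:
        raise ValidationError(report.message or "invalid input")

    stats = FilterStats(read=len(records), written=len(records))
    if config.prefilter:
        records, stats = seqio.prefilter_reads(records)

    summary: dict = {"filter_stats": stats, "input_reads": stats.read,
                     "screened_reads": len(records)}
    out_format = config.out_format
    if out_format is None:
        out_format = "fastq" if records and all(
            r.qual is not None for r in records) else "fasta"
    compression = "gzip" if config.gzip else "none"

    if not records:
        summary.update(counts={l: 0 for l in ("clean", "contamination", "both")},
                       percent_contamination=0.0,
                       warning="no reads survived prefiltering")
        for label in ("clean", "contamination", "both"):
            ext = out_format + (".gz" if config.gzip else "")
            seqio.write_sequences([], f"{config.out_prefix}_{label}.{ext}",
                                  format=out_format, compression=compression)
        return summary

    remove_indexes = _load_databases(config.remove_dbs, "remove", config)
    retain_indexes = _load_databases(config.retain_dbs, "retain", config)
    classifications, remove_hits, retain_hits = screen_reads(
        records, remove_indexes, retain_indexes, config.thresholds,
        config.params, retain_all=config.retain_all, workers=config.workers)

    counts = split_output(records, classifications, config.out_prefix,
                          format=out_format, compression=compression,
                          joined_retained=True, retain_both=config.retain_both)
    plot_data = build_plot_data(classifications)
    Path(f"{config.out_prefix}_plotdata.txt").write_text(plot_data.to_text())
    write_hits_tsv(remove_hits.values(), f"{config.out_prefix}_remove_hits.tsv")
    if retain_indexes:
        write_hits_tsv(retain_hits.values(),
                       f"{config.out_prefix}_retain_hits.tsv")

    n = len(records)
    pct = 100.0 * counts["contamination"] / n
    if not config.retain_both:
        pct = 100.0 * (counts["contamination"] + counts["both"]) / n
    summary.update(counts={l: counts[l] for l in
                           ("clean", "contamination", "both")},
                   retained=counts.get("retained"),
                   percent_contamination=pct)
    lines = [f"reads_in\t{stats.read}", f"reads_screened\t{n}"]
    lines += [f"{l}\t{counts[l]}" for l in ("clean", "contamination", "both")]
    lines.append(f"percent_contamination\t{pct:.4f}")
    Path(f"{config.out_prefix}_summary.txt").write_text(
        "".join(x + "\n" for x in lines))
    return summary
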