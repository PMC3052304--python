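"""Synthetic genomes and simulated reads with full ground truth.

Stands in for the human/bacterial/viral reference data: seeded i.i.d.
genomes (with optional planted N runs and duplicated segments), a
metagenome read simulator with an independent per-base error model
(defaults: 0.85% substitutions + 0.15% 1-bp indels, normally distributed
read lengths with mean 380 bp and SD 100 bp, minimum 100 bp, unique
N-free reads), fixed-length tiling at 50% overlap for sensitivity
benchmarks, and an exact-count error injector (total errors = round(rate
x length), 15% of them indels) for worst-case error-rate experiments.

Every read carries its origin and the edit script's substitution /
insertion / deletion counts, so classifier output can be scored against
construction-time truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .refdb import revcomp
from .seqio import SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulatedRead:
    record: SequenceRecord
    source_id: str
    start: int            # 0-based start on the source genome (forward strand)
    strand: str           # '+' | '-'
    label: str            # 'contaminant' | 'non-contaminant'
    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0


def _role_to_label(role: str) -> str:
    return "contaminant" if role == "remove" else "non-contaminant"


def make_synthetic_genome(length: int,
                          gc: float = 0.5,
                          seed: int = 0,
                          n_stretches: Optional[Sequence[tuple[int, int]]] = None,
                          repeat_insertions: int = 0,
                          id: str = "synth1") -> SequenceRecord:
    """Seeded i.i.d. genome at a given GC content.

    ``n_stretches``: (0-based position, length) N runs planted after the
    random draw; overlapping stretches are rejected.  ``repeat_insertions``
    copies of a random internal segment are pasted elsewhere (overwriting)
    to create exact repeats.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    arr = _BASES[codes].copy()
    for _ in range(repeat_insertions):
        seg_len = max(100, min(1000, length // 10))
        if length < 2 * seg_len:
            break
        src = int(rng.integers(0, length - seg_len + 1))
        dst = int(rng.integers(0, length - seg_len + 1))
        arr[dst:dst + seg_len] = arr[src:src + seg_len].copy()
    if n_stretches:
        taken: list[tuple[int, int]] = []
        for pos, run in n_stretches:
            if pos < 0 or pos + run > length:
                raise ValueError(f"N stretch ({pos}, {run}) out of bounds")
            for p0, r0 in taken:
                if pos < p0 + r0 and p0 < pos + run:
                    raise ValueError("overlapping N stretches")
            taken.append((pos, run))
            arr[pos:pos + run] = ord("N")
    return SequenceRecord(id=id, seq=arr.tobytes().decode("ascii"))


def _apply_errors(seq: str, rng: np.random.Generator,
                  sub_rate: float, indel_rate: float
                  ) -> tuple[str, int, int, int]:
    """Independent per-base errors: substitutions first, then 1-bp indels
    (insertion or deletion equally likely)."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    base_codes = lut[codes]
    n_sub = n_ins = n_del = 0
    if sub_rate > 0:
        subs = np.flatnonzero((rng.random(len(codes)) < sub_rate)
                              & (base_codes < 4))
        if len(subs):
            shift = rng.integers(1, 4, size=len(subs))
            codes[subs] = _BASES[(base_codes[subs] + shift) % 4]
            n_sub = len(subs)
    if indel_rate > 0:
        events = rng.random(len(codes)) < indel_rate
        kind = rng.random(len(codes)) < 0.5  # True: insertion, False: deletion
        reps = np.ones(len(codes), dtype=np.int64)
        reps[events & ~kind] = 0
        out = np.repeat(codes, reps)
        ins_pos = np.flatnonzero(events & kind)
        if len(ins_pos):
            # map to positions in the deletion-applied array, insert before
            offsets = np.cumsum(reps) - reps
            ins_bases = _BASES[rng.integers(0, 4, size=len(ins_pos))]
            out = np.insert(out, offsets[ins_pos], ins_bases)
        n_ins = int(len(ins_pos))
        n_del = int(np.sum(events & ~kind))
        codes = out
    return codes.tobytes().decode("ascii"), n_sub, n_ins, n_del


def simulate_reads(genomes: Sequence[tuple[SequenceRecord, str]],
                   n: int,
                   sub_rate: float = 0.0085,
                   indel_rate: float = 0.0015,
                   len_mean: float = 380.0,
                   len_sd: float = 100.0,
                   min_len: int = 100,
                   unique: bool = True,
                   no_n: bool = True,
                   seed: int = 0,
                   id_prefix: str = "read") -> list[SimulatedRead]:
    """Draw ``n`` reads uniformly over loci of the given (genome, role) set.

    Start positions and strands are uniform; lengths are normal draws
    rounded to integers and redrawn while < ``min_len`` or > the source
    length.  Errors are independent per-base events at the given rates.
    Uniqueness and N-freedom are enforced by rejection resampling.
    """
    if not genomes:
        raise ValueError("no genomes supplied")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= sub_rate < 1 and 0 <= indel_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    weights = np.array([len(g.seq) for g, _ in genomes], dtype=float)
    weights /= weights.sum()
    seen: set[str] = set()
    reads: list[SimulatedRead] = []
    max_tries = 100 * n
    tries = 0
    while len(reads) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not draw {n} qualifying reads after {max_tries} tries "
                "(genomes too short or too repetitive)")
        gi = int(rng.choice(len(genomes), p=weights))
        genome, role = genomes[gi]
        glen = len(genome.seq)
        length = int(round(rng.normal(len_mean, len_sd)))
        if length < min_len or length > glen:
            continue
        start = int(rng.integers(0, glen - length + 1))
        segment = genome.seq[start:start + length]
        if no_n and "N" in segment:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            segment = revcomp(segment)
        seq, n_sub, n_ins, n_del = _apply_errors(segment, rng, sub_rate,
                                                 indel_rate)
        if no_n and "N" in seq:
            continue
        if unique:
            if seq in seen:
                continue
            seen.add(seq)
        rid = f"{id_prefix}{len(reads):06d}"
        reads.append(SimulatedRead(
            record=SequenceRecord(id=rid, seq=seq),
            source_id=genome.id, start=start, strand=strand,
            label=_role_to_label(role),
            n_sub=n_sub, n_ins=n_ins, n_del=n_del))
    return reads


def tile_reads(genome: SequenceRecord,
               read_len: int,
               overlap: float = 0.5,
               role: str = "remove",
               id_prefix: str = "tile") -> list[SimulatedRead]:
    """Fixed-length windows across a genome at the given overlap.

    Windows start at multiples of ``read_len * (1 - overlap)``; only
    full-length windows are emitted, any window containing an N is
    discarded, forward strand only.
    """
    if read_len < 2:
        raise ValueError("read_len must be >= 2")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    step = int(round(read_len * (1 - overlap)))
    if step < 1:
        raise ValueError("overlap too large for this read length")
    out: list[SimulatedRead] = []
    glen = len(genome.seq)
    k = 0
    for start in range(0, glen - read_len + 1, step):
        window = genome.seq[start:start + read_len]
        if "N" in window:
            continue
        out.append(SimulatedRead(
            record=SequenceRecord(id=f"{id_prefix}{k:06d}", seq=window),
            source_id=genome.id, start=start, strand="+",
            label=_role_to_label(role)))
        k += 1
    return out


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def inject_errors_exact(read: SimulatedRead,
                        rate: float,
                        indel_frac: float = 0.15,
                        seed: int = 0) -> SimulatedRead:
    """Introduce an exact total number of errors into a read.

    E = round(rate * length) errors at uniformly drawn distinct
    positions; round(indel_frac * E) of them are 1-bp indels (insertion
    or deletion equally likely), the rest substitutions.
    """
    seq = read.record.seq
    if rate > 0.5:
        raise ValueError("error rate above 0.5 is not supported")
    e_total = _round_half_up(rate * len(seq))
    if e_total == 0:
        return read
    rng = np.random.default_rng(seed)
    n_indel = _round_half_up(indel_frac * e_total)
    n_sub = e_total - n_indel
    positions = rng.choice(len(seq), size=e_total, replace=False)
    rng.shuffle(positions)
    sub_pos = sorted(int(p) for p in positions[:n_sub])
    indel_pos = sorted((int(p) for p in positions[n_sub:]), reverse=True)
    arr = list(seq)
    lut = {b: i for i, b in enumerate("ACGT")}
    n_ins = n_del = 0
    for p in sub_pos:
        old = lut.get(arr[p], rng.integers(0, 4))
        arr[p] = "ACGT"[(old + int(rng.integers(1, 4))) % 4]
    for p in indel_pos:  # descending: earlier positions stay valid
        if rng.random() < 0.5:
            arr.insert(p, "ACGT"[int(rng.integers(0, 4))])
            n_ins += 1
        else:
            del arr[p]
            n_del += 1
    rec = SequenceRecord(id=read.record.id, seq="".join(arr))
    return SimulatedRead(record=rec, source_id=read.source_id,
                         start=read.start, strand=read.strand,
                         label=read.label,
                         n_sub=read.n_sub + len(sub_pos),
                         n_ins=read.n_ins + n_ins,
                         n_del=read.n_del + n_del)


# ---------------------------------------------------------------------------
# ground-truth I/O

_TRUTH_HEADER = "read_id\tsource_id\tstart\tstrand\tlabel\tn_sub\tn_ins\tn_del"


def write_truth_tsv(reads: Iterable[SimulatedRead],
                    sink: Union[str, Path, None] = None) -> str:
    lines = [_TRUTH_HEADER]
    for r in reads:
        lines.append(f"{r.record.id}\t{r.source_id}\t{r.start}\t{r.strand}"
                     f"\t{r.label}\t{r.n_sub}\t{r.n_ins}\t{r.n_del}")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        Path(sink).write_text(text)
    return text


def read_truth_labels(source: Union[str, Path]) -> dict[str, str]:
    """read id -> truth label from a ground-truth TSV."""
    text = Path(source).read_text()
    out: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        fields = line.split("\t")
        out[fields[0]] = fields[4]
    return out
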