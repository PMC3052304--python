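"""Reading, writing, validating and prefiltering DNA sequence data.

FASTA and FASTQ are handled through Bio.SeqIO; this module adds the
behaviours the screening workflow needs on top of it: automatic format
and compression sniffing (plain, GZIP, ZIP — multi-member archives are
joined into a single stream), strict DNA validation over the IUPAC
nucleotide alphabet, and the read prefilter (length window, ambiguous
base fraction after flank-N trimming, exact-duplicate removal, optional
poly-A/T tail trimming).

Sequences are upper-cased on read; FASTQ qualities are carried through
verbatim but never interpreted.
"""

from __future__ import annotations

import gzip
import io
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide one-letter codes (uppercase).
IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN")

#: Concrete (unambiguous) bases.
CONCRETE_BASES = frozenset("ACGTU")

Source = Union[str, Path, IO]


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input; names the offending record."""


@dataclass(frozen=True)
class SequenceRecord:
    """One read or reference sequence.

    id: non-empty whitespace-free identifier.
    seq: DNA string over the IUPAC nucleotide codes (uppercase).
    qual: optional per-base quality string (Phred+33), same length as seq.
    """

    id: str
    seq: str
    qual: Optional[str] = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class FilterStats:
    """Bookkeeping for :func:`prefilter_reads`.

    Invariant: ``read == written + removed_short + removed_long +
    removed_n + removed_duplicate``.  ``trimmed`` counts surviving records
    whose sequence was modified and is not part of the conservation sum.
    """

    read: int = 0
    removed_short: int = 0
    removed_long: int = 0
    removed_n: int = 0
    removed_duplicate: int = 0
    trimmed: int = 0
    written: int = 0

    def check(self) -> None:
        removed = (self.removed_short + self.removed_long +
                   self.removed_n + self.removed_duplicate)
        if self.read != self.written + removed:
            raise AssertionError(f"FilterStats conservation violated: {self}")

    def to_report(self) -> str:
        """Serialize as flat ``key<TAB>value`` lines."""
        keys = ("read", "removed_short", "removed_long", "removed_n",
                "removed_duplicate", "trimmed", "written")
        return "".join(f"{k}\t{getattr(self, k)}\n" for k in keys)


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    n_records: int = 0
    message: Optional[str] = None


# ---------------------------------------------------------------------------
# reading

_GZIP_MAGIC = b"\x1f\x8b"
_ZIP_MAGIC = b"PK\x03\x04"


def _sniff_compression(path: Path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head[:2] == _GZIP_MAGIC:
        return "gzip"
    if head[:4] == _ZIP_MAGIC:
        return "zip"
    return "none"


def _sniff_format(handle: IO[str]) -> Optional[str]:
    """Peek at the first non-blank character: '>' fasta, '@' fastq.

    Returns None for an empty (or all-blank) stream, which parses as zero
    records; any other leading character is a parse error.
    """
    pos = handle.tell()
    ch = None
    while True:
        ch = handle.read(1)
        if not ch or not ch.isspace():
            break
    handle.seek(pos)
    if not ch:
        return None
    fmt = {"@": "fastq", ">": "fasta"}.get(ch)
    if fmt is None:
        raise ParseError("cannot detect sequence format "
                         "(file does not start with '>' or '@')")
    return fmt


def _to_record(rec: SeqRecord, fmt: str) -> SequenceRecord:
    seq = str(rec.seq).upper()
    qual = None
    if fmt == "fastq":
        phred = rec.letter_annotations.get("phred_quality")
        if phred is not None:
            qual = "".join(chr(q + 33) for q in phred)
    if not rec.id:
        raise ParseError("record with empty identifier")
    if not seq:
        raise ParseError(f"record {rec.id!r} has an empty sequence")
    return SequenceRecord(id=rec.id, seq=seq, qual=qual)


def _parse_handle(handle: IO[str], fmt: str) -> Iterator[SequenceRecord]:
    if fmt == "auto":
        fmt = _sniff_format(handle)
        if fmt is None:
            return
    # skip leading blank lines (tolerated on input, rejected by Bio)
    while True:
        pos = handle.tell()
        line = handle.readline()
        if not line:
            return
        if line.strip():
            handle.seek(pos)
            break
    last = "<start of file>"
    try:
        for rec in SeqIO.parse(handle, fmt):
            out = _to_record(rec, fmt)
            last = out.id
            yield out
    except ValueError as exc:  # Bio.SeqIO signals malformed records this way
        raise ParseError(f"malformed {fmt} record after {last!r}: {exc}") from exc


def read_sequences(source: Source, format: str = "auto",
                   compression: str = "auto") -> Iterator[SequenceRecord]:
    """Yield :class:`SequenceRecord` from FASTA/FASTQ, in file order.

    Format and compression are auto-detected by default.  A ZIP archive
    containing several sequence files is joined into one stream, member
    by member in archive order.
    """
    if hasattr(source, "read"):  # file-like: assume uncompressed text
        handle = source
        if isinstance(handle.read(0), bytes):
            handle = io.TextIOWrapper(handle)
        yield from _parse_handle(handle, format)
        return

    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    comp = compression
    if comp == "auto":
        comp = _sniff_compression(path)
    if comp == "none":
        with open(path, "rt") as fh:
            yield from _parse_handle(fh, format)
    elif comp == "gzip":
        with gzip.open(path, "rt") as fh:
            yield from _parse_handle(fh, format)
    elif comp == "zip":
        with zipfile.ZipFile(path) as zf:
            names = [n for n in zf.namelist() if not n.endswith("/")]
            for name in names:
                with zf.open(name) as raw:
                    fh = io.TextIOWrapper(raw)
                    yield from _parse_handle(fh, format)
    else:
        raise ValueError(f"unknown compression {compression!r}")


# ---------------------------------------------------------------------------
# writing

def _to_bio(rec: SequenceRecord, fmt: str) -> SeqRecord:
    out = SeqRecord(Seq(rec.seq), id=rec.id, description="")
    if fmt == "fastq":
        if rec.qual is None:
            raise ValueError(f"record {rec.id!r} has no quality string; "
                             "cannot write fastq")
        if len(rec.qual) != len(rec.seq):
            raise ValueError(f"record {rec.id!r}: quality length mismatch")
        out.letter_annotations["phred_quality"] = [ord(c) - 33 for c in rec.qual]
    return out


def write_sequences(records: Iterable[SequenceRecord], sink: Union[str, Path, IO],
                    format: str = "fasta", compression: str = "none") -> int:
    """Write records to ``sink``; returns the number written.

    FASTA output is wrapped at 60 columns (a fixed dialect so that
    write-then-read round trips are byte-stable).
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported output format {format!r}")

    def _dump(handle: IO[str]) -> int:
        n = 0
        if format == "fasta":
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
            for rec in records:
                writer.write_record(_to_bio(rec, format))
                n += 1
        else:
            for rec in records:
                SeqIO.write(_to_bio(rec, format), handle, "fastq")
                n += 1
        return n

    if hasattr(sink, "write"):
        return _dump(sink)
    path = Path(sink)
    opener = gzip.open if compression == "gzip" else open
    if compression not in ("none", "gzip"):
        raise ValueError(f"unsupported output compression {compression!r}")
    with opener(path, "wt") as fh:
        return _dump(fh)


# ---------------------------------------------------------------------------
# validation and prefiltering

def validate_dna(records: Iterable[SequenceRecord]) -> ValidationReport:
    """Check every record against the DNA invariants; report-returning.

    Empty input is not valid ("checked to be a valid file with DNA data"
    presumes there is data).
    """
    n = 0
    for rec in records:
        n += 1
        if not rec.id or any(c.isspace() for c in rec.id):
            return ValidationReport(False, n, f"record {n}: bad identifier {rec.id!r}")
        if len(rec.seq) < 1:
            return ValidationReport(False, n, f"record {rec.id!r}: empty sequence")
        for ch in rec.seq:
            if ch.upper() not in IUPAC_CODES:
                return ValidationReport(
                    False, n,
                    f"record {rec.id!r}: invalid character {ch!r}")
        if rec.qual is not None and len(rec.qual) != len(rec.seq):
            return ValidationReport(
                False, n, f"record {rec.id!r}: quality length mismatch")
    if n == 0:
        return ValidationReport(False, 0, "no records in input")
    return ValidationReport(True, n, None)


def _trim_flank_n(rec: SequenceRecord) -> SequenceRecord:
    seq = rec.seq
    start = 0
    while start < len(seq) and seq[start] == "N":
        start += 1
    end = len(seq)
    while end > start and seq[end - 1] == "N":
        end -= 1
    if start == 0 and end == len(seq):
        return rec
    qual = rec.qual[start:end] if rec.qual is not None else None
    return replace(rec, seq=seq[start:end], qual=qual)


def _trim_poly_at(rec: SequenceRecord, cutoff: int) -> SequenceRecord:
    """Trim maximal terminal mono-A or mono-T runs strictly longer than cutoff."""
    seq = rec.seq
    start, end = 0, len(seq)
    for base in "AT":
        run = 0
        while run < end - start and seq[start + run] == base:
            run += 1
        if run > cutoff:
            start += run
        run = 0
        while run < end - start and seq[end - 1 - run] == base:
            run += 1
        if run > cutoff:
            end -= run
    if start == 0 and end == len(seq):
        return rec
    qual = rec.qual[start:end] if rec.qual is not None else None
    return replace(rec, seq=seq[start:end], qual=qual)


def _ambiguous_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    n_amb = sum(1 for c in seq if c not in CONCRETE_BASES)
    return n_amb / len(seq)


def prefilter_reads(records: Iterable[SequenceRecord],
                    min_len: int = 50,
                    max_len: int = 10000,
                    max_n_frac: float = 0.05,
                    trim_flank_n: bool = True,
                    dedup_exact: bool = True,
                    trim_polyAT_over: Optional[int] = None,
                    ) -> tuple[list[SequenceRecord], FilterStats]:
    """Apply the metagenome read prefilter.

    Trimming (flank Ns, then poly-A/T tails when enabled) happens before
    the length and ambiguous-fraction tests.  Duplicates are byte-identical
    post-trim sequences; the first occurrence is kept.  Order preserved.
    """
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")
    if not (0.0 <= max_n_frac <= 1.0):
        raise ValueError("max_n_frac must be in [0, 1]")

    stats = FilterStats()
    seen: set[str] = set()
    kept: list[SequenceRecord] = []
    for rec in records:
        stats.read += 1
        trimmed = rec
        if trim_flank_n:
            trimmed = _trim_flank_n(trimmed)
        if trim_polyAT_over is not None:
            trimmed = _trim_poly_at(trimmed, trim_polyAT_over)
        was_trimmed = trimmed.seq != rec.seq
        if len(trimmed.seq) < min_len:
            stats.removed_short += 1
            continue
        if len(trimmed.seq) > max_len:
            stats.removed_long += 1
            continue
        if _ambiguous_fraction(trimmed.seq) > max_n_frac:
            stats.removed_n += 1
            continue
        if dedup_exact:
            if trimmed.seq in seen:
                stats.removed_duplicate += 1
                continue
            seen.add(trimmed.seq)
        if was_trimmed:
            stats.trimmed += 1
        stats.written += 1
        kept.append(trimmed)
    stats.check()
    return kept, stats
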