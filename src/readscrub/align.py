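"""Seed-and-extend local alignment against FM-indexed reference chunks.

Reads are anchored by exact k-mer seeds found with backward search on the
FM-index (both strands; k-mers containing N or occurring more often than
the repeat cap yield no seeds), seeds on nearby diagonals are clustered,
and each candidate cluster is extended by a banded affine-gap local
Smith-Waterman alignment.  Alignment columns are classified with an
extended CIGAR distinguishing M (match) from R (replacement): a column is
M only when the bases are equal, the query base is a concrete A/C/G/T and
the reference position was not an ambiguity code before indexing — so a
randomly concretized reference N can never manufacture identity, and an N
in the query is always forced to a mismatch.

Query coverage and alignment identity, the two quantities the classifier
thresholds, are derived from the extended CIGAR alone::

    coverage = 100 * (M + R + I) / query_length
    identity = 100 * M / (M + R + I + D)

The identity denominator includes indel columns; this choice is isolated
here in :func:`compute_coverage_identity`.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np

from ._kernels import NEG, banded_sw_fill
from .refdb import FMIndex, encode_query, revcomp
from .seqio import SequenceRecord


@dataclass(frozen=True)
class AlignerParams:
    """Engine parameters.

    Scoring mirrors BWA-SW's defaults (match +1, mismatch 3, gap open 5,
    gap extend 2; a gap of length L costs open + L*ext).  ``z`` is the
    number of best-scoring candidates retained per read before the single
    best is chosen; ``max_candidates`` caps how many seed clusters are
    extended (an engine throughput knob, not a contract).
    """

    k: int = 12
    max_occ: int = 500
    band: int = 50
    match: int = 1
    mismatch: int = 3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: int = 30
    z: int = 1
    max_candidates: int = 8

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if min(self.mismatch, self.gap_open, self.gap_extend) <= 0:
            raise ValueError("penalties must be positive")
        if self.z < 1:
            raise ValueError("z must be >= 1")


@dataclass
class AlignmentHit:
    """One local alignment of a read against a reference sequence.

    Intervals are 0-based half-open; the query interval is on the
    original read, while the CIGAR reads in the aligned orientation
    (reverse-complemented read for '-' strand hits).
    """

    query_id: str
    ref_id: str
    coverage: float
    identity: float
    strand: str = "+"
    qstart: int = 0
    qend: int = 0
    rstart: int = 0
    rend: int = 0
    score: int = 0
    cigar: str = ""
    query_len: int = 0


_CIGAR_RE = re.compile(r"(\d+)([MRID])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    if not cigar:
        raise ValueError("empty CIGAR")
    runs = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in runs) != cigar:
        raise ValueError(f"malformed extended CIGAR {cigar!r}")
    return [(int(n), op) for n, op in runs]


def cigar_counts(cigar: str) -> dict[str, int]:
    counts = {"M": 0, "R": 0, "I": 0, "D": 0}
    for n, op in parse_cigar(cigar):
        counts[op] += n
    return counts


def compute_coverage_identity(cigar: str, query_len: int) -> tuple[float, float]:
    """Coverage and identity percentages from an extended CIGAR.

    coverage = 100*(M+R+I)/query_len, identity = 100*M/(M+R+I+D); both
    returned as unrounded reals.
    """
    if query_len <= 0:
        raise ValueError("query_len must be positive")
    c = cigar_counts(cigar)
    aligned_q = c["M"] + c["R"] + c["I"]
    columns = aligned_q + c["D"]
    if columns == 0:
        raise ValueError("CIGAR aligns no columns")
    return 100.0 * aligned_q / query_len, 100.0 * c["M"] / columns


def _runs_to_cigar(ops: Sequence[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


# ---------------------------------------------------------------------------
# seeding

def _seed_arrays(query_codes: np.ndarray, index: FMIndex, params: AlignerParams
                 ) -> tuple[np.ndarray, np.ndarray]:
    """All seed occurrences of one strand: (query offsets, text positions)."""
    m = len(query_codes)
    k = params.k
    if m < k:
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    kmers = np.lib.stride_tricks.sliding_window_view(query_codes, k)
    top, bot = index.search_batch(np.ascontiguousarray(kmers))
    occ = bot - top
    use = (occ > 0) & (occ <= params.max_occ)
    idx = np.flatnonzero(use)
    if not len(idx):
        return (np.empty(0, np.int64), np.empty(0, np.int64))
    rows = np.concatenate([np.arange(top[i], bot[i]) for i in idx])
    qoffs = np.repeat(idx, occ[idx])
    positions = index.locate_rows(rows)
    return qoffs.astype(np.int64), positions


def find_seeds(query: SequenceRecord, index: FMIndex, params: AlignerParams
               ) -> list[tuple[int, int, str]]:
    """Exact k-mer seed matches of the read and its reverse complement.

    Returns (query offset, text position, strand) tuples; for '-' strand
    the offset is on the reverse-complemented read (the orientation the
    extension aligns).
    """
    out: list[tuple[int, int, str]] = []
    for strand, seq in (("+", query.seq), ("-", revcomp(query.seq))):
        qoffs, positions = _seed_arrays(encode_query(seq), index, params)
        out.extend((int(q), int(p), strand) for q, p in zip(qoffs, positions))
    return out


# ---------------------------------------------------------------------------
# extension

def _extend_window(query_codes: np.ndarray, index: FMIndex, seq_idx: int,
                   diag: int, spread: int, params: AlignerParams
                   ) -> Optional[tuple]:
    """Banded SW of the (oriented) query around a diagonal of one sequence.

    ``diag`` is the sequence-local diagonal (ref offset - query offset);
    ``spread`` widens the band to cover a cluster's diagonal range.
    Returns (score, qstart, qend, local_rstart, local_rend, cigar) or None.
    """
    m = len(query_codes)
    seq_start, seq_end = index.seq_bounds(seq_idx)
    seq_len = seq_end - seq_start
    bw = params.band + spread // 2 + 1
    win_lo = max(0, diag - bw)
    win_hi = min(seq_len, diag + m + bw)
    if win_hi <= win_lo:
        return None
    w = index.text[seq_start + win_lo: seq_start + win_hi]
    wmask = index.amb_mask[seq_start + win_lo: seq_start + win_hi]
    d0 = diag - win_lo
    H, F, E, bi, bb, best = banded_sw_fill(
        query_codes, w, wmask, d0, bw,
        params.match, params.mismatch, params.gap_open, params.gap_extend)
    if best < params.min_score:
        return None
    ops, qs, js = _traceback(H, F, E, query_codes, w, wmask, d0, bw, bi, bb,
                             params)
    je = bi + d0 + bb - bw
    return int(best), qs, bi, win_lo + js, win_lo + je, _runs_to_cigar(ops)


def _traceback(H, F, E, q, w, wmask, d0, bw, i, b, params: AlignerParams):
    """Recover the alignment path from the filled band matrices.

    Preference order at score ties: diagonal, then vertical (I), then
    horizontal (D) — fixed for deterministic output.
    """
    width = 2 * bw + 1
    goe = params.gap_open + params.gap_extend
    ops: list[str] = []
    state = "H"
    while True:
        if state == "H":
            h = H[i, b]
            if h == 0:
                break
            j = i + d0 + b - bw
            qc = q[i - 1]
            wc = w[j - 1]
            is_match = (qc == wc) and qc < 4 and not wmask[j - 1]
            sub = params.match if is_match else -params.mismatch
            hd = H[i - 1, b]
            if hd > NEG and h == hd + sub:
                ops.append("M" if is_match else "R")
                i -= 1
            elif h == F[i, b]:
                state = "F"
            elif h == E[i, b]:
                state = "E"
            else:  # pragma: no cover - would indicate a kernel bug
                raise AssertionError("inconsistent traceback")
        elif state == "F":
            ops.append("I")
            f = F[i, b]
            hup = H[i - 1, b + 1] if b + 1 < width else NEG
            closes = hup > NEG and f == hup - goe
            i -= 1
            b += 1
            if closes:
                state = "H"
        else:  # "E"
            ops.append("D")
            e = E[i, b]
            hl = H[i, b - 1] if b - 1 >= 0 else NEG
            closes = hl > NEG and e == hl - goe
            b -= 1
            if closes:
                state = "H"
    ops.reverse()
    return ops, i, i + d0 + b - bw


def _make_hit(query: SequenceRecord, index: FMIndex, seq_idx: int, strand: str,
              ext: tuple) -> AlignmentHit:
    score, qs, qe, rs, re_, cigar = ext
    m = len(query.seq)
    if strand == "-":
        qs, qe = m - qe, m - qs
    coverage, identity = compute_coverage_identity(cigar, m)
    return AlignmentHit(
        query_id=query.id, ref_id=index.ids[seq_idx], coverage=coverage,
        identity=identity, strand=strand, qstart=qs, qend=qe,
        rstart=rs, rend=re_, score=score, cigar=cigar, query_len=m)


def extend_seed(query: SequenceRecord, index: FMIndex,
                seed: tuple[int, int, str], params: AlignerParams
                ) -> Optional[AlignmentHit]:
    """Extend a single seed into a local alignment (or None below min score)."""
    qoff, pos, strand = seed
    codes = encode_query(query.seq if strand == "+" else revcomp(query.seq))
    seq_idx, local = index.pos_to_ref(pos)
    ext = _extend_window(codes, index, seq_idx, local - qoff, 0, params)
    if ext is None:
        return None
    return _make_hit(query, index, seq_idx, strand, ext)


def _clusters(qoffs: np.ndarray, positions: np.ndarray, index: FMIndex,
              band: int) -> list[tuple[int, int, int, int]]:
    """Group seed occurrences of one strand by (sequence, diagonal).

    Returns (seq_idx, median diag, spread, n_seeds) per cluster, largest
    clusters first.
    """
    if not len(qoffs):
        return []
    seq_idx = np.searchsorted(index.starts, positions, side="right") - 1
    local = positions - index.starts[seq_idx]
    diag = local - qoffs
    order = np.lexsort((diag, seq_idx))
    s, d = seq_idx[order], diag[order]
    breaks = np.flatnonzero((s[1:] != s[:-1]) | (np.diff(d) > band // 2)) + 1
    bounds = np.concatenate([[0], breaks, [len(d)]])
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        dmin, dmax = int(d[a]), int(d[b - 1])
        out.append((int(s[a]), (dmin + dmax) // 2, dmax - dmin, int(b - a)))
    out.sort(key=lambda c: (-c[3], c[0], c[1]))
    return out


def _hit_sort_key(hit: AlignmentHit):
    return (-hit.score, -hit.identity, hit.ref_id, hit.rstart)


def align_read(query: SequenceRecord, indexes: Sequence[FMIndex],
               params: Optional[AlignerParams] = None,
               return_all: bool = False
               ) -> Union[Optional[AlignmentHit], list[AlignmentHit]]:
    """Best local alignment of a read against a set of index chunks.

    Candidates from all chunks and both strands are merged, overlapping
    candidates deduplicated, the top ``z`` by score retained and the
    single best returned (ties: higher identity, then lexicographically
    smaller reference id, then smaller reference coordinate).
    """
    params = params or AlignerParams()
    hits: list[AlignmentHit] = []
    codes = {"+": encode_query(query.seq), "-": encode_query(revcomp(query.seq))}
    for index in indexes:
        for strand in ("+", "-"):
            qoffs, positions = _seed_arrays(codes[strand], index, params)
            for seq_idx, diag, spread, _n in \
                    _clusters(qoffs, positions, index, params.band)[:params.max_candidates]:
                ext = _extend_window(codes[strand], index, seq_idx, diag,
                                     spread, params)
                if ext is not None:
                    hits.append(_make_hit(query, index, seq_idx, strand, ext))
    hits = _dedup_overlapping(hits)
    hits.sort(key=_hit_sort_key)
    hits = hits[: params.z]
    if return_all:
        return hits
    return hits[0] if hits else None


def _dedup_overlapping(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep the best of any group of hits to the same reference/strand with
    overlapping reference intervals."""
    hits = sorted(hits, key=lambda h: (h.ref_id, h.strand, h.rstart))
    out: list[AlignmentHit] = []
    group_end = -1
    for h in hits:
        if out and out[-1].ref_id == h.ref_id and out[-1].strand == h.strand \
                and h.rstart < group_end:
            group_end = max(group_end, h.rend)
            if _hit_sort_key(h) < _hit_sort_key(out[-1]):
                out[-1] = h
        else:
            out.append(h)
            group_end = h.rend
    return out


# ---------------------------------------------------------------------------
# hit I/O: lightweight TSV and SAM

def write_hits_tsv(hits: Iterable[AlignmentHit],
                   sink: Union[str, Path, IO, None] = None) -> str:
    """Serialize hits as the lightweight 4-column format:
    query_id <TAB> ref_id <TAB> coverage <TAB> identity (2 decimals)."""
    text = "".join(
        f"{h.query_id}\t{h.ref_id}\t{h.coverage:.2f}\t{h.identity:.2f}\n"
        for h in hits)
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            Path(sink).write_text(text)
    return text


def read_hits_tsv(source: Union[str, Path, IO]) -> list[AlignmentHit]:
    """Parse the lightweight TSV back into (partial) hits."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path) or (
            "\n" not in str(source) and "\t" not in str(source)
            and os.path.exists(str(source))):
        text = Path(source).read_text()
    else:
        text = str(source)
    hits = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"line {lineno}: expected 4 tab-separated "
                             f"fields, got {len(fields)}")
        qid, rid, cov, ident = fields
        try:
            hits.append(AlignmentHit(query_id=qid, ref_id=rid,
                                     coverage=float(cov), identity=float(ident)))
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return hits


_SAM_EXT_OP = {7: "M", 8: "R", 1: "I", 2: "D"}


def read_hits_sam(path: Union[str, Path]) -> list[AlignmentHit]:
    """Read hits from a SAM file whose CIGARs distinguish matches ('=')
    from replacements ('X'); plain 'M' is rejected as ambiguous."""
    import pysam

    hits = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.cigartuples is None:
                continue
            ops = []
            for op, n in rec.cigartuples:
                if op in (4, 5):  # clips reduce coverage implicitly
                    continue
                ext = _SAM_EXT_OP.get(op)
                if ext is None:
                    raise ValueError(
                        f"read {rec.query_name}: CIGAR operator "
                        f"{op} cannot be mapped to M/R (need '='/'X')")
                ops.extend([ext] * n)
            cigar = _runs_to_cigar(ops)
            qlen = rec.infer_read_length() or len(rec.query_sequence or "")
            cov, ident = compute_coverage_identity(cigar, qlen)
            hits.append(AlignmentHit(
                query_id=rec.query_name, ref_id=rec.reference_name,
                coverage=cov, identity=ident,
                strand="-" if rec.is_reverse else "+",
                rstart=rec.reference_start, rend=rec.reference_end,
                cigar=cigar, query_len=qlen))
    return hits


def write_hits_sam(hits: Iterable[AlignmentHit],
                   sink: Union[str, Path, IO],
                   ref_lengths: dict[str, int]) -> int:
    """Minimal SAM output with '='/'X' CIGAR operators (1-based POS)."""
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for rid, length in ref_lengths.items():
        lines.append(f"@SQ\tSN:{rid}\tLN:{length}")
    n = 0
    for h in hits:
        flag = 16 if h.strand == "-" else 0
        sam_cigar = ""
        lead = h.qstart if h.strand == "+" else h.query_len - h.qend
        tail = h.query_len - h.qend if h.strand == "+" else h.qstart
        if lead:
            sam_cigar += f"{lead}S"
        sam_cigar += h.cigar.replace("M", "=").replace("R", "X")
        if tail:
            sam_cigar += f"{tail}S"
        lines.append("\t".join([
            h.query_id, str(flag), h.ref_id, str(h.rstart + 1), "255",
            sam_cigar, "*", "0", "0", "*", "*", f"AS:i:{h.score}"]))
        n += 1
    text = "\n".join(lines) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)
    return n
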