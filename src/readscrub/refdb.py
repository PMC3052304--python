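"""Reference database preprocessing and FM-indexing.

Reference genomes destined for a "remove" (contaminant) or "retain"
(protected) database are cleaned before indexing: sequences are split at
long stretches of ambiguous bases (N runs of >= 200 by default, since
those positions would otherwise be randomly replaced at indexing time and
could manufacture false matches), deduplicated, filtered for a high
ambiguous-base fraction, and packed into chunks of bounded size that are
indexed independently and searched jointly.

The index is a plain FM-index: Burrows-Wheeler transform over the
concatenated chunk text (one unique sentinel per sequence, so matches
never span sequences), full occurrence table for the four bases, and a
suffix array sampled by text position.  Residual ambiguity codes are
replaced by a seeded-random concrete base and remembered in an ambiguity
mask; the aligner scores masked positions as mismatches.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqio import SequenceRecord, FilterStats, read_sequences, write_sequences

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}
#: code used for any position that is not a concrete A/C/G/T (query side)
N_CODE = 4

#: IUPAC ambiguity code -> candidate concrete bases (for randomized replacement)
_AMBIG = {
    "N": "ACGT", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


def encode_query(seq: str) -> np.ndarray:
    """Encode a read: A/C/G/T -> 0..3, anything else -> N_CODE."""
    table = np.full(256, N_CODE, dtype=np.int8)
    for b, c in _BASE_TO_CODE.items():
        table[ord(b)] = c
        table[ord(b.lower())] = c
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTURYSWKMBDHVNacgturyswkmbdhvn",
                          "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn")


# ---------------------------------------------------------------------------
# reference preprocessing

def split_at_n_stretches(record: SequenceRecord, min_stretch: int = 200
                         ) -> list[SequenceRecord]:
    """Split a sequence at runs of >= ``min_stretch`` Ns.

    Parts are renamed ``<origid>.<k>`` (1-based over non-empty parts);
    a record without any qualifying run is returned unchanged.
    """
    if min_stretch < 1:
        raise ValueError("min_stretch must be >= 1")
    parts = split_with_offsets(record, min_stretch)
    if len(parts) == 1 and parts[0][1].seq == record.seq:
        return [record]
    return [rec for _, rec in parts]


def split_with_offsets(record: SequenceRecord, min_stretch: int = 200
                       ) -> list[tuple[int, SequenceRecord]]:
    """Like :func:`split_at_n_stretches` but each part carries its 0-based
    start offset in the original sequence."""
    pattern = re.compile("N{%d,}" % min_stretch)
    out: list[tuple[int, SequenceRecord]] = []
    pos = 0
    k = 0
    pieces: list[tuple[int, str]] = []
    for m in pattern.finditer(record.seq):
        pieces.append((pos, record.seq[pos:m.start()]))
        pos = m.end()
    pieces.append((pos, record.seq[pos:]))
    if len(pieces) == 1:
        return [(0, record)]
    for start, seq in pieces:
        if not seq:
            continue
        k += 1
        out.append((start, SequenceRecord(id=f"{record.id}.{k}", seq=seq)))
    return out


def filter_reference(records: Iterable[SequenceRecord],
                     max_n_frac: float = 0.05,
                     dedup: bool = True,
                     min_len: int = 1,
                     ) -> tuple[list[SequenceRecord], FilterStats]:
    """Drop reference sequences that are too short, too ambiguous
    (strictly more than ``max_n_frac`` non-ACGT bases) or exact duplicates
    of an earlier kept sequence."""
    if not (0.0 <= max_n_frac <= 1.0):
        raise ValueError("max_n_frac must be in [0, 1]")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    stats = FilterStats()
    seen: set[str] = set()
    kept: list[SequenceRecord] = []
    for rec in records:
        stats.read += 1
        if len(rec.seq) < min_len:
            stats.removed_short += 1
            continue
        n_amb = sum(1 for c in rec.seq if c not in "ACGT")
        if n_amb / len(rec.seq) > max_n_frac:
            stats.removed_n += 1
            continue
        if dedup:
            if rec.seq in seen:
                stats.removed_duplicate += 1
                continue
            seen.add(rec.seq)
        stats.written += 1
        kept.append(rec)
    stats.check()
    return kept, stats


@dataclass
class ReferenceChunk:
    """A bounded-size group of preprocessed reference sequences."""
    chunk_id: str
    records: list[SequenceRecord]
    role: str = "remove"  # "remove" | "retain"

    @property
    def total_bases(self) -> int:
        return sum(len(r.seq) for r in self.records)


def chunk_reference(records: Sequence[SequenceRecord],
                    max_bases_per_chunk: int,
                    role: str = "remove",
                    prefix: str = "chunk") -> list[ReferenceChunk]:
    """Pack sequences into chunks of at most ``max_bases_per_chunk`` bases,
    sequentially in input order; a single oversize sequence gets its own
    chunk (sequences are never split)."""
    if max_bases_per_chunk < 1:
        raise ValueError("max_bases_per_chunk must be >= 1")
    chunks: list[ReferenceChunk] = []
    current: list[SequenceRecord] = []
    current_bases = 0
    for rec in records:
        if current and current_bases + len(rec.seq) > max_bases_per_chunk:
            chunks.append(ReferenceChunk(f"{prefix}{len(chunks) + 1}", current, role))
            current, current_bases = [], 0
        current.append(rec)
        current_bases += len(rec.seq)
    if current:
        chunks.append(ReferenceChunk(f"{prefix}{len(chunks) + 1}", current, role))
    return chunks


# ---------------------------------------------------------------------------
# suffix array (prefix doubling on integer codes)

def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling (O(n log n))."""
    n = len(codes)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    k = 1
    sa = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        combined = rank * (n + 1) + (key2 + 1)
        sa = np.argsort(combined, kind="stable")
        ordered = combined[sa]
        newrank = np.zeros(n, dtype=np.int64)
        newrank[1:] = np.cumsum(ordered[1:] != ordered[:-1])
        rank = np.empty(n, dtype=np.int64)
        rank[sa] = newrank
        if newrank[-1] == n - 1:
            break
        k *= 2
    return sa


# ---------------------------------------------------------------------------
# FM-index

@dataclass
class FMIndex:
    """FM-index over one reference chunk.

    Text layout: seq_0, SEP_0, seq_1, SEP_1, ..., seq_{s-1}, SEP_{s-1}.
    Sentinels get the unique codes 0..s-1 (so each is its own character
    and LF through a sentinel is trivial); bases are coded s..s+3.
    The public ``text`` array instead holds 0..3 for bases and 255 for
    sentinels, which is what the aligner consumes directly.
    """

    ids: list[str]
    starts: np.ndarray          # int64, start offset of each sequence in text
    lengths: np.ndarray         # int64
    text: np.ndarray            # uint8: 0..3 bases, 255 sentinels
    bwt: np.ndarray             # int64 codes (sentinel codes + shifted bases)
    occ: np.ndarray             # int64 (4, n+1): base occurrence counts in bwt
    counts: np.ndarray          # int64 (4,): total count per base
    sa_mask: np.ndarray         # bool, rows whose suffix position is sampled
    sa_rank: np.ndarray         # int64, prefix count of sampled rows
    sa_vals: np.ndarray         # int64, sampled suffix positions
    amb_mask: np.ndarray        # bool, text positions that were ambiguity codes
    seed: int
    sa_stride: int
    role: str = "remove"
    chunk_id: str = "chunk1"

    # -- derived helpers ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.text)

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    def _c(self, base: int) -> int:
        # rank offset of base code: sentinels first, then bases in order
        return self.n_seqs + int(np.sum(self.counts[:base]))

    def count(self, pattern: str) -> int:
        top, bot = self.search(pattern)
        return bot - top

    def search(self, pattern: str) -> tuple[int, int]:
        """Backward search; returns the half-open BWT row interval."""
        codes = encode_query(pattern)
        if np.any(codes >= 4):
            return (0, 0)
        top, bot = 0, self.n
        cvec = np.array([self._c(b) for b in range(4)], dtype=np.int64)
        for c in codes[::-1]:
            top = cvec[c] + self.occ[c, top]
            bot = cvec[c] + self.occ[c, bot]
            if top >= bot:
                return (0, 0)
        return (int(top), int(bot))

    def search_batch(self, kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Backward search of many same-length patterns at once.

        kmers: (nk, k) int8 array of query codes; any code >= 4 kills the
        k-mer.  Returns (top, bot) int64 arrays; dead k-mers have top==bot.
        """
        nk, k = kmers.shape
        cvec = np.array([self._c(b) for b in range(4)], dtype=np.int64)
        top = np.zeros(nk, dtype=np.int64)
        bot = np.full(nk, self.n, dtype=np.int64)
        alive = ~np.any(kmers >= 4, axis=1)
        bot[~alive] = 0
        for j in range(k - 1, -1, -1):
            if not alive.any():
                break
            c = kmers[alive, j].astype(np.int64)
            idx = np.flatnonzero(alive)
            top[idx] = cvec[c] + self.occ[c, top[idx]]
            bot[idx] = cvec[c] + self.occ[c, bot[idx]]
            dead = top[idx] >= bot[idx]
            if dead.any():
                didx = idx[dead]
                bot[didx] = top[didx]
                alive[didx] = False
        return top, bot

    def locate_rows(self, rows: np.ndarray) -> np.ndarray:
        """Resolve BWT rows to text positions via the sampled suffix array."""
        rows = np.asarray(rows, dtype=np.int64)
        pos = np.full(len(rows), -1, dtype=np.int64)
        cur = rows.copy()
        steps = np.zeros(len(rows), dtype=np.int64)
        unresolved = np.arange(len(rows))
        cvec = np.array([self._c(b) for b in range(4)], dtype=np.int64)
        while len(unresolved):
            r = cur[unresolved]
            hit = self.sa_mask[r]
            if hit.any():
                h = unresolved[hit]
                pos[h] = self.sa_vals[self.sa_rank[cur[h]]] + steps[h]
                unresolved = unresolved[~hit]
                if not len(unresolved):
                    break
                r = cur[unresolved]
            # one LF step backwards through the text
            b = self.bwt[r]
            is_sent = b < self.n_seqs
            nxt = np.empty(len(r), dtype=np.int64)
            nxt[is_sent] = b[is_sent]  # unique sentinel: LF(row) = code
            if (~is_sent).any():
                bases = b[~is_sent] - self.n_seqs
                rr = r[~is_sent]
                nxt[~is_sent] = cvec[bases] + self.occ[bases, rr]
            cur[unresolved] = nxt
            steps[unresolved] += 1
        return pos

    def locate(self, pattern: str) -> np.ndarray:
        """All 0-based text positions of exact occurrences (sorted)."""
        top, bot = self.search(pattern)
        if top >= bot:
            return np.empty(0, dtype=np.int64)
        return np.sort(self.locate_rows(np.arange(top, bot)))

    def pos_to_ref(self, pos: int) -> tuple[int, int]:
        """Map a text position to (sequence index, offset within sequence)."""
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        return i, int(pos - self.starts[i])

    def seq_bounds(self, seq_idx: int) -> tuple[int, int]:
        s = int(self.starts[seq_idx])
        return s, s + int(self.lengths[seq_idx])

    # -- serialization ------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Serialize as a directory of plain-text files."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "role": self.role,
            "chunk_id": self.chunk_id,
            "seed": self.seed,
            "sa_stride": self.sa_stride,
            "ids": self.ids,
            "lengths": [int(x) for x in self.lengths],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        # cleaned text (post ambiguity replacement) as FASTA
        recs = []
        for i, rid in enumerate(self.ids):
            s, e = self.seq_bounds(i)
            seq = "".join(_BASES[c] for c in self.text[s:e])
            recs.append(SequenceRecord(id=rid, seq=seq))
        write_sequences(recs, d / "sequences.fasta", format="fasta")
        np.savetxt(d / "ambiguity_mask.txt",
                   np.flatnonzero(self.amb_mask), fmt="%d")
        bwt_rows = np.flatnonzero(self.sa_mask)
        np.savetxt(d / "sa_samples.txt",
                   np.column_stack([bwt_rows, self.sa_vals]), fmt="%d")
        np.savetxt(d / "bwt.txt", self.bwt, fmt="%d")

    @classmethod
    def load(cls, directory: str | Path) -> "FMIndex":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        recs = list(read_sequences(d / "sequences.fasta"))
        mask_text = (d / "ambiguity_mask.txt").read_text().split()
        amb_pos = np.array([int(x) for x in mask_text], dtype=np.int64)
        chunk = ReferenceChunk(manifest["chunk_id"], recs, manifest["role"])
        idx = build_index(chunk, seed=manifest["seed"],
                          sa_stride=manifest["sa_stride"])
        # sequences were already concretized; restore the recorded mask
        idx.amb_mask[:] = False
        if len(amb_pos):
            idx.amb_mask[amb_pos] = True
        return idx


def build_index(chunk: ReferenceChunk, seed: int = 0,
                sa_stride: int = 32) -> FMIndex:
    """Build the FM-index for one chunk.

    Residual ambiguity codes are replaced by a seeded-random concrete base
    (uniform over the code's candidate set) and recorded in the ambiguity
    mask so the aligner can refuse to score them as matches.
    """
    if not chunk.records:
        raise ValueError("cannot index an empty chunk")
    rng = np.random.default_rng(seed)
    s = len(chunk.records)
    pieces: list[np.ndarray] = []
    mask_pieces: list[np.ndarray] = []
    ids, lengths, starts = [], [], []
    pos = 0
    for i, rec in enumerate(chunk.records):
        seq = rec.seq.upper()
        codes = encode_query(seq).astype(np.uint8)
        amb = codes >= 4
        for j in np.flatnonzero(amb):
            ch = seq[j]
            cands = _AMBIG.get(ch)
            if cands is None:
                raise ValueError(
                    f"sequence {rec.id!r}: non-IUPAC character {ch!r}")
            codes[j] = _BASE_TO_CODE[cands[rng.integers(len(cands))]]
        ids.append(rec.id)
        starts.append(pos)
        lengths.append(len(seq))
        pieces.append(codes)
        mask_pieces.append(amb)
        pos += len(seq) + 1  # +1 for the sentinel

    n = pos
    text = np.full(n, 255, dtype=np.uint8)
    amb_mask = np.zeros(n, dtype=bool)
    sort_codes = np.empty(n, dtype=np.int64)
    for i in range(s):
        st, ln = starts[i], lengths[i]
        text[st:st + ln] = pieces[i]
        amb_mask[st:st + ln] = mask_pieces[i]
        sort_codes[st:st + ln] = pieces[i].astype(np.int64) + s
        sort_codes[st + ln] = i  # unique sentinel code

    sa = suffix_array(sort_codes)
    bwt = sort_codes[(sa - 1) % n]
    # occurrence table for the four bases only
    occ = np.zeros((4, n + 1), dtype=np.int64)
    for b in range(4):
        occ[b, 1:] = np.cumsum(bwt == b + s)
    counts = occ[:, -1].copy()

    sampled = (sa % sa_stride) == 0
    sa_rank = np.zeros(n, dtype=np.int64)
    sa_rank[1:] = np.cumsum(sampled[:-1])
    return FMIndex(
        ids=ids,
        starts=np.asarray(starts, dtype=np.int64),
        lengths=np.asarray(lengths, dtype=np.int64),
        text=text, bwt=bwt, occ=occ, counts=counts,
        sa_mask=sampled, sa_rank=sa_rank, sa_vals=sa[sampled].astype(np.int64),
        amb_mask=amb_mask, seed=int(seed), sa_stride=int(sa_stride),
        role=chunk.role, chunk_id=chunk.chunk_id,
    )


def build_database(records: Iterable[SequenceRecord],
                   role: str = "remove",
                   seed: int = 0,
                   min_n_stretch: int = 200,
                   max_n_frac: float = 0.05,
                   min_len: int = 1,
                   max_bases_per_chunk: int = 10_000_000,
                   sa_stride: int = 32) -> list[FMIndex]:
    """Full preprocessing pipeline: N-split, filter, chunk, index.

    Returns one FM-index per chunk; chunks of one database are searched
    jointly and their results joined by the aligner.
    """
    split: list[SequenceRecord] = []
    for rec in records:
        split.extend(split_at_n_stretches(rec, min_n_stretch))
    kept, _ = filter_reference(split, max_n_frac=max_n_frac, min_len=min_len)
    chunks = chunk_reference(kept, max_bases_per_chunk, role=role)
    return [build_index(c, seed=seed + i, sa_stride=sa_stride)
            for i, c in enumerate(chunks)]
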