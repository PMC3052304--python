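"""Reference preprocessing and FM-index correctness."""

import numpy as np
import pytest

import readscrub as rs
from conftest import random_dna
from oracle import naive_occurrences
from readscrub.refdb import split_with_offsets, suffix_array


class TestSplitAtNStretches:
    def test_split_at_long_run(self):
        seq = "A" * 400 + "N" * 250 + "C" * 350  # run at 1-based 401-650
        parts = rs.split_at_n_stretches(rs.SequenceRecord("chr", seq))
        assert [(p.id, len(p.seq)) for p in parts] == \
            [("chr.1", 400), ("chr.2", 350)]

    def test_short_run_left_alone(self):
        seq = "A" * 100 + "N" * 150 + "C" * 100
        rec = rs.SequenceRecord("chr", seq)
        assert rs.split_at_n_stretches(rec) == [rec]

    def test_all_n_gives_empty_list(self):
        assert rs.split_at_n_stretches(rs.SequenceRecord("chr", "N" * 300)) == []

    def test_leading_run_dropped_and_numbering_over_kept_parts(self):
        seq = "N" * 200 + "ACGT" * 100 + "N" * 200 + "TTTT" * 50
        parts = rs.split_at_n_stretches(rs.SequenceRecord("chr", seq))
        assert [p.id for p in parts] == ["chr.1", "chr.2"]

    def test_reconstruction_invariant(self, rng):
        # restoring the removed N runs at the recorded offsets reproduces
        # the input, and no part retains a qualifying run
        seq = list(random_dna(rng, 3000))
        for pos, run in [(100, 200), (700, 350), (2500, 499)]:
            seq[pos:pos + run] = "N" * run
        seq = "".join(seq)
        rec = rs.SequenceRecord("g", seq)
        parts = split_with_offsets(rec, 200)
        rebuilt = list("N" * len(seq))
        for start, part in parts:
            rebuilt[start:start + len(part.seq)] = part.seq
        assert "".join(rebuilt) == seq
        for _, part in parts:
            assert "N" * 200 not in part.seq


class TestFilterReference:
    @pytest.mark.parametrize("n_amb, kept", [(6, False), (5, True)])
    def test_ambiguity_boundary_is_strict(self, n_amb, kept):
        seq = "N" * n_amb + "ACGT" * ((100 - n_amb) // 4) + "A" * ((100 - n_amb) % 4)
        out, _ = rs.filter_reference([rs.SequenceRecord("r", seq)])
        assert bool(out) is kept

    def test_duplicates_and_min_len(self):
        recs = [rs.SequenceRecord("a", "ACGT" * 100),
                rs.SequenceRecord("b", "ACGT" * 100),
                rs.SequenceRecord("c", "ACGTACGT")]
        out, stats = rs.filter_reference(recs, min_len=300)
        assert [r.id for r in out] == ["a"]
        assert stats.removed_duplicate == 1 and stats.removed_short == 1


class TestChunkReference:
    def test_sequential_packing(self):
        recs = [rs.SequenceRecord(f"r{i}", "A" * 1000) for i in range(10)]
        chunks = rs.chunk_reference(recs, 3000)
        assert [len(c.records) for c in chunks] == [3, 3, 3, 1]
        assert [r.id for c in chunks for r in c.records] == \
            [f"r{i}" for i in range(10)]

    def test_oversize_record_gets_own_chunk(self):
        chunks = rs.chunk_reference([rs.SequenceRecord("big", "A" * 5000)], 3000)
        assert len(chunks) == 1 and chunks[0].total_bases == 5000

    def test_empty_input(self):
        assert rs.chunk_reference([], 1000) == []


class TestSuffixArray:
    def test_matches_naive_sort(self, rng):
        for n in (1, 2, 17, 200):
            t = rng.integers(0, 5, n).astype(np.int64)
            t[-1] = -1  # unique terminator
            sa = suffix_array(t)
            naive = sorted(range(n), key=lambda i: list(t[i:]))
            assert list(sa) == naive


class TestFMIndex:
    def test_locate_example(self):
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord("s", "TACGACG")]), seed=0)
        assert list(idx.locate("ACG")) == [1, 4]
        assert idx.count("GGG") == 0

    def test_backward_search_equals_naive_scan(self, rng):
        text = random_dna(rng, 10_000)
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord("s", text)]), seed=0)
        for _ in range(100):
            i = int(rng.integers(0, len(text) - 8))
            pat = text[i:i + 8]
            assert list(idx.locate(pat)) == naive_occurrences(pat, text)

    def test_matches_never_span_sequences(self):
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord("a", "AAAATTTT"),
                                    rs.SequenceRecord("b", "TTTTAAAA")]), seed=0)
        # "TTTTTTTT" only exists across the boundary
        assert idx.count("TTTTTTTT") == 0
        assert idx.count("TTTT") == 2

    def test_lf_mapping_reconstructs_text(self):
        seqs = ["ACGTACGGT", "TTACG"]
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord(f"s{i}", s)
                                    for i, s in enumerate(seqs)]), seed=0)
        s = idx.n_seqs
        cvec = [idx._c(b) for b in range(4)]
        for i, seq in enumerate(seqs):
            row = i  # suffix starting at sentinel i sorts at rank i
            rebuilt = []
            while True:
                b = int(idx.bwt[row])
                if b < s:  # previous sentinel or text start
                    break
                base = b - s
                rebuilt.append("ACGT"[base])
                row = cvec[base] + int(idx.occ[base, row])
            assert "".join(reversed(rebuilt)) == seq

    def test_ambiguity_replacement_recorded_and_seeded(self):
        rec = rs.SequenceRecord("s", "ACGTNNRYACGT")
        a = rs.build_index(rs.ReferenceChunk("c", [rec]), seed=7)
        b = rs.build_index(rs.ReferenceChunk("c", [rec]), seed=7)
        other = rs.build_index(rs.ReferenceChunk("c", [rec]), seed=8)
        assert np.array_equal(a.text, b.text)
        assert list(np.flatnonzero(a.amb_mask)) == [4, 5, 6, 7]
        assert np.all(a.text[4:8] < 4)  # concretized
        assert other.seed != a.seed
        # R must be replaced by a purine
        assert "ACGT"[a.text[6]] in "AG"

    def test_non_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            rs.build_index(
                rs.ReferenceChunk("c", [rs.SequenceRecord("s", "ACXT")]), seed=0)

    def test_serialization_round_trip_and_determinism(self, tmp_path, rng):
        text = random_dna(rng, 2000) + "N" * 10 + random_dna(rng, 500)
        rec = rs.SequenceRecord("s", text)
        idx = rs.build_index(rs.ReferenceChunk("c1", [rec]), seed=3)
        idx.save(tmp_path / "db")
        idx2 = rs.FMIndex.load(tmp_path / "db")
        assert np.array_equal(idx.bwt, idx2.bwt)
        assert np.array_equal(idx.amb_mask, idx2.amb_mask)
        pat = text[100:115]
        assert list(idx2.locate(pat)) == list(idx.locate(pat))
        # same inputs + seed -> byte-identical serialized form
        idx2.save(tmp_path / "db2")
        for name in ("manifest.json", "sequences.fasta", "bwt.txt",
                     "sa_samples.txt", "ambiguity_mask.txt"):
            assert (tmp_path / "db" / name).read_bytes() == \
                (tmp_path / "db2" / name).read_bytes()


def test_build_database_pipeline(rng):
    left, right = random_dna(rng, 1200), random_dna(rng, 800)
    genome = rs.SequenceRecord("chr1", left + "N" * 250 + right)
    dup = rs.SequenceRecord("chr2", left + "N" * 250 + right)
    indexes = rs.build_database([genome, dup], role="retain", seed=0,
                                max_bases_per_chunk=1500)
    ids = [rid for idx in indexes for rid in idx.ids]
    assert ids == ["chr1.1", "chr1.2"]  # chr2 parts removed as duplicates
    assert all(idx.role == "retain" for idx in indexes)
    assert len(indexes) == 2  # 1200 + 800 > 1500 forces two chunks
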