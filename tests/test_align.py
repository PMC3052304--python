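"""Alignment engine: seeding, banded extension, coverage/identity, hit I/O."""

import io

import numpy as np
import pytest

import readscrub as rs
from conftest import random_dna
from oracle import naive_kmer_seeds, sw_local_score

PARAMS = rs.AlignerParams()


def _mutate(seq, pos):
    return seq[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]] \
        + seq[pos + 1:]


class TestCoverageIdentity:
    @pytest.mark.parametrize("cigar, qlen, cov, ident", [
        ("100M", 100, 100.0, 100.0),
        ("90M5R5I", 100, 100.0, 90.0),
        ("45M5R", 100, 50.0, 90.0),
        ("50M2D50M", 100, 100.0, 100.0 * 100 / 102),
    ])
    def test_formulas(self, cigar, qlen, cov, ident):
        c, i = rs.compute_coverage_identity(cigar, qlen)
        assert c == pytest.approx(cov)
        assert i == pytest.approx(ident)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            rs.compute_coverage_identity("100M", 0)
        with pytest.raises(ValueError):
            rs.compute_coverage_identity("", 100)
        with pytest.raises(ValueError):
            rs.compute_coverage_identity("10M3S", 100)


class TestFindSeeds:
    def test_exact_substring_yields_dense_plus_seeds(self, small_genome,
                                                     small_index):
        read = rs.SequenceRecord("q", small_genome.seq[2000:2500])
        seeds = rs.find_seeds(read, small_index, PARAMS)
        plus = [s for s in seeds if s[2] == "+"]
        assert len(plus) >= 500 // PARAMS.k

    def test_all_n_read_has_no_seeds(self, small_index):
        read = rs.SequenceRecord("q", "N" * 500)
        assert rs.find_seeds(read, small_index, PARAMS) == []

    def test_seeds_match_brute_force_kmer_scan(self, rng):
        text = random_dna(rng, 3000)
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord("s", text)]), seed=0)
        read = text[500:580]
        seeds = rs.find_seeds(rs.SequenceRecord("q", read), idx, PARAMS)
        got = {(q, p) for q, p, strand in seeds if strand == "+"}
        assert got == naive_kmer_seeds(read, text, PARAMS.k)

    def test_high_occurrence_kmers_skipped(self):
        text = "ACGTACGTACGT" * 600  # every 12-mer occurs ~600 times
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord("s", text)]), seed=0)
        read = rs.SequenceRecord("q", text[:100])
        assert rs.find_seeds(read, idx, PARAMS) == []


class TestExtendSeed:
    def test_exact_copy_scores_match_per_base(self, small_genome, small_index):
        read = rs.SequenceRecord("q", small_genome.seq[1000:1300])
        hit = rs.extend_seed(read, small_index, (0, 1000, "+"), PARAMS)
        assert hit.cigar == "300M"
        assert hit.score == 300 * PARAMS.match
        assert (hit.qstart, hit.qend) == (0, 300)
        assert (hit.rstart, hit.rend) == (1000, 1300)

    def test_single_substitution_gives_one_replacement(self, small_genome,
                                                       small_index):
        read = rs.SequenceRecord("q", _mutate(small_genome.seq[1000:1300], 150))
        hit = rs.extend_seed(read, small_index, (0, 1000, "+"), PARAMS)
        assert hit.cigar == "150M1R149M"

    def test_query_n_against_reference_n_is_replacement(self):
        # reference N is randomly concretized but masked; a query N above it
        # must classify as R, never M
        ref = "ACGTACGTAC" * 6 + "N" + "GTACGTACGT" * 6
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord("s", ref)]), seed=5)
        read = rs.SequenceRecord("q", ref)  # query keeps its N
        hit = rs.align_read(read, [idx], PARAMS)
        assert hit.cigar == "60M1R60M"

    def test_masked_reference_position_never_matches(self):
        # even a query base equal to the random replacement scores R
        ref = "ACGTACGTAC" * 6 + "N" + "GTACGTACGT" * 6
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord("s", ref)]), seed=5)
        concrete = "ACGT"[idx.text[60]]
        read = rs.SequenceRecord("q", ref.replace("N", concrete))
        hit = rs.align_read(read, [idx], PARAMS)
        assert hit.cigar == "60M1R60M"


class TestAlignRead:
    def test_error_free_substring_full_coverage_identity(self, small_genome,
                                                         small_index):
        read = rs.SequenceRecord("q", small_genome.seq[10_000:10_500])
        hit = rs.align_read(read, [small_index], PARAMS)
        assert hit.coverage == 100.0 and hit.identity == 100.0
        assert hit.strand == "+"

    def test_reverse_complement_hits_minus_strand(self, small_genome,
                                                  small_index):
        read = rs.SequenceRecord("q", rs.revcomp(small_genome.seq[20_000:20_400]))
        hit = rs.align_read(read, [small_index], PARAMS)
        assert hit.strand == "-" and hit.identity == 100.0
        assert (hit.rstart, hit.rend) == (20_000, 20_400)

    def test_random_read_has_no_passing_hit(self, small_index, rng):
        t = rs.Thresholds(95, 94)
        for _ in range(5):
            read = rs.SequenceRecord("q", random_dna(rng, 500))
            hit = rs.align_read(read, [small_index], PARAMS)
            assert hit is None or not rs.passes_thresholds(hit, t)

    def test_hits_joined_across_chunks(self, rng):
        a, b = random_dna(rng, 2000), random_dna(rng, 2000)
        idxs = rs.build_database(
            [rs.SequenceRecord("A", a), rs.SequenceRecord("B", b)],
            max_bases_per_chunk=2000)
        assert len(idxs) == 2
        for src, rid in ((a, "A"), (b, "B")):
            hit = rs.align_read(rs.SequenceRecord("q", src[300:600]), idxs,
                                PARAMS)
            assert hit.ref_id == rid and hit.coverage == 100.0

    def test_engine_score_equals_full_dp_oracle(self, rng):
        # homologous read planted in a random reference: the engine's
        # banded, seeded extension must recover the unbanded optimum
        for trial in range(8):
            n = int(rng.integers(500, 2000))
            ref = random_dna(rng, n)
            start = int(rng.integers(0, n - 200))
            seg = list(ref[start:start + 180])
            for p in rng.choice(len(seg), size=6, replace=False):
                seg[p] = "ACGT"[("ACGT".index(seg[p]) +
                                 int(rng.integers(1, 4))) % 4]
            for _ in range(2):  # small indels stay inside the band
                p = int(rng.integers(10, len(seg) - 10))
                if rng.random() < 0.5:
                    seg.insert(p, "ACGT"[int(rng.integers(0, 4))])
                else:
                    del seg[p]
            read = "".join(seg)
            idx = rs.build_index(
                rs.ReferenceChunk("c", [rs.SequenceRecord("r", ref)]), seed=0)
            hit = rs.align_read(rs.SequenceRecord("q", read), [idx], PARAMS)
            oracle = max(sw_local_score(read, ref),
                         sw_local_score(rs.revcomp(read), ref))
            assert hit is not None and hit.score == oracle

    def test_substitutions_never_increase_identity(self, small_genome,
                                                   small_index, rng):
        read = small_genome.seq[30_000:30_380]
        positions = rng.choice(380, size=12, replace=False)
        last = 100.0
        for k in (0, 3, 6, 12):
            mutated = read
            for p in sorted(int(x) for x in positions[:k]):
                mutated = _mutate(mutated, p)
            hit = rs.align_read(rs.SequenceRecord("q", mutated),
                                [small_index], PARAMS)
            assert hit is not None
            assert hit.identity <= last + 1e-9
            last = hit.identity

    def test_tie_break_is_deterministic(self, rng):
        seg = random_dna(rng, 120)
        ref = random_dna(rng, 500) + seg + random_dna(rng, 500) + seg \
            + random_dna(rng, 200)
        idx = rs.build_index(
            rs.ReferenceChunk("c", [rs.SequenceRecord("r", ref)]), seed=0)
        hit = rs.align_read(rs.SequenceRecord("q", seg), [idx], PARAMS)
        assert hit.rstart == 500  # equal scores: lower coordinate wins


class TestHitIO:
    def test_tsv_format_contract(self):
        hit = rs.AlignmentHit("r1", "chrA", 95.25, 97.1)
        assert rs.write_hits_tsv([hit]) == "r1\tchrA\t95.25\t97.10\n"
        assert rs.write_hits_tsv([]) == ""

    def test_tsv_round_trip_field_identity(self, rng):
        hits = [rs.AlignmentHit(f"q{i}", f"ref{i % 7}",
                                float(np.round(rng.uniform(0, 100), 2)),
                                float(np.round(rng.uniform(0, 100), 2)))
                for i in range(1000)]
        back = rs.read_hits_tsv(rs.write_hits_tsv(hits))
        assert [(h.query_id, h.ref_id, h.coverage, h.identity) for h in back] \
            == [(h.query_id, h.ref_id, h.coverage, h.identity) for h in hits]

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            rs.read_hits_tsv("a\tb\t1.00\t2.00\noops\n")

    def test_sam_round_trip_and_m_rejection(self, tmp_path, small_genome,
                                            small_index):
        read = rs.SequenceRecord("q", _mutate(small_genome.seq[1000:1300], 150))
        hit = rs.align_read(read, [small_index], PARAMS)
        sam = tmp_path / "hits.sam"
        rs.write_hits_sam([hit], sam, {small_genome.id: len(small_genome.seq)})
        back = rs.read_hits_sam(sam)
        assert len(back) == 1
        assert back[0].coverage == pytest.approx(hit.coverage)
        assert back[0].identity == pytest.approx(hit.identity)
        bad = tmp_path / "bad.sam"
        bad.write_text("@HD\tVN:1.6\n@SQ\tSN:r\tLN:100\n"
                       "q\t0\tr\t1\t255\t10M\t*\t0\t0\tACGTACGTAC\t*\n")
        with pytest.raises(ValueError, match="M/R"):
            rs.read_hits_sam(bad)
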