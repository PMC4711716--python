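"""Seed extension DP, qualification, and the single-/paired-end cascades."""

import numpy as np
import pytest
from oracles import rc, sliding_edit_distance, sw_score

from blockalign.alignment_core import (
    AlignmentRecord,
    QualificationParams,
    ScoringParams,
    align_paired,
    align_single,
    is_qualified,
    local_align,
    pair_seeds,
    rank_seeds,
    rescue_mate,
    semiglobal_align,
)
from blockalign.io_formats import ReadRecord
from blockalign.reference_index import Seed, find_mem_seeds

SCORING = ScoringParams()
QUAL = QualificationParams()


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng, seq, n_subs):
    out = list(seq)
    for j in rng.choice(len(seq), size=n_subs, replace=False):
        out[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[j]]
    return "".join(out)


class TestLocalAlign:
    def test_identity_scores_match_times_length(self):
        score, pos, cigar = local_align("ACGTACGTAC", "ACGTACGTAC",
                                        ScoringParams(match=2))
        assert (score, pos, cigar) == (20, 0, "10M")

    def test_all_mismatch_floors_at_zero(self):
        score, _, cigar = local_align("AAAA", "TTTT", SCORING)
        assert score == 0
        assert "M" not in cigar

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT", SCORING)

    def test_banded_equals_unbanded_oracle_on_random_pairs(self, rng):
        """With the band covering the whole matrix, the banded DP must equal
        a textbook full-matrix Smith-Waterman."""
        wide = ScoringParams(band_width=128)
        for _ in range(200):
            m = int(rng.integers(20, 101))
            n = int(rng.integers(20, 101))
            if rng.random() < 0.5:  # related pair: mutated copy
                a = _random_seq(rng, m)
                b = _mutate(rng, a, int(rng.integers(0, m // 4)))[:n]
                if not b:
                    b = "A"
            else:
                a, b = _random_seq(rng, m), _random_seq(rng, n)
            score, _, _ = local_align(a, b, wide)
            assert score == sw_score(a, b, 1, -3, -5, -2)


class TestSemiglobalAlign:
    def test_exact_interior_match(self, rng):
        window = _random_seq(rng, 200)
        read = window[57:117]
        score, pos, cigar, edits = semiglobal_align(read, window, SCORING)
        assert (pos, cigar, edits) == (57, "60M", 0)
        assert score == 60

    def test_edit_count_matches_sliding_oracle(self, rng):
        pytest.importorskip("edlib")
        for _ in range(100):
            window = _random_seq(rng, int(rng.integers(60, 200)))
            if rng.random() < 0.6:
                start = int(rng.integers(0, len(window) - 50))
                read = _mutate(rng, window[start : start + 50],
                               int(rng.integers(0, 8)))
            else:
                read = _random_seq(rng, 50)
            _, _, _, edits = semiglobal_align(read, window, SCORING)
            assert edits == sliding_edit_distance(read, window)

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            semiglobal_align("", "ACGT", SCORING)

    def test_window_shorter_than_read_rejected(self):
        with pytest.raises(ValueError):
            semiglobal_align("ACGTACGT", "ACGT", SCORING)


class TestRankSeeds:
    def test_singleton_gets_its_score(self, index_2kb, genome_2kb):
        _, seq = genome_2kb
        read = seq[500:600]
        seeds = find_mem_seeds(index_2kb, read, 19)
        ranked = rank_seeds(index_2kb, read, seeds[:1], SCORING, 8)
        assert len(ranked) == 1
        assert ranked[0].rank_score == 100

    def test_empty_input_gives_empty_output(self, index_2kb):
        assert rank_seeds(index_2kb, "ACGT" * 10, [], SCORING, 8) == []

    def test_order_matches_recomputed_oracle_scores(self, index_2kb, genome_2kb, rng):
        """Ranking must equal an independent recompute-and-sort: for each
        seed, full-DP score of the read against the seed's window."""
        _, seq = genome_2kb
        for _ in range(15):
            pos = int(rng.integers(0, len(seq) - 80))
            read = _mutate(rng, seq[pos : pos + 80], int(rng.integers(0, 6)))
            seeds = find_mem_seeds(index_2kb, read, 14)
            if not seeds:
                continue
            ranked = rank_seeds(index_2kb, read, seeds, SCORING, 8)
            band = SCORING.band_width
            expected = []
            for s in seeds:
                oriented = read if s.strand == "+" else rc(read)
                ws = max(0, s.genome_pos - s.read_offset - band)
                we = min(len(seq), s.genome_pos - s.read_offset + len(read) + 2 * band)
                expected.append(
                    (sw_score(oriented, seq[ws:we], 1, -3, -5, -2),
                     s.genome_pos, s.read_offset)
                )
            expected.sort(key=lambda t: (-t[0], t[1], t[2]))
            got = [(s.rank_score, s.genome_pos, s.read_offset) for s in ranked]
            assert got == expected[:8]


def _local_record(score, cigar, read_len):
    return AlignmentRecord(
        read_id="q", ref_name="chr", pos=0, strand="+", cigar=cigar,
        score=score, stage="LOCAL", qualified=False, mapq=0,
        seq="A" * read_len, qual="I" * read_len,
    )


class TestQualification:
    def test_perfect_alignment_qualifies(self):
        rec = _local_record(100, "100M", 100)
        assert is_qualified(rec, 100, QUAL, match=1)

    def test_boundary_score_passes(self):
        rec = _local_record(30, "80M20S", 100)  # exactly 0.30 * 100 and 0.80 cover
        assert is_qualified(rec, 100, QUAL, match=1)

    def test_zero_score_fails(self):
        rec = _local_record(0, "100M", 100)
        assert not is_qualified(rec, 100, QUAL, match=1)

    def test_coverage_below_fraction_fails(self):
        rec = _local_record(50, "79M21S", 100)
        assert not is_qualified(rec, 100, QUAL, match=1)

    def test_edit_stage_uses_edit_fraction(self):
        rec = _local_record(50, "100M", 100)
        rec.stage = "SEMIGLOBAL"
        rec.edits = 10
        assert is_qualified(rec, 100, QUAL)
        rec.edits = 11
        assert not is_qualified(rec, 100, QUAL)

    def test_unaligned_rejected(self):
        rec = _local_record(0, "100M", 100)
        rec.stage = "UNALIGNED"
        with pytest.raises(ValueError):
            is_qualified(rec, 100, QUAL)


class TestAlignSingle:
    def test_planted_identity_read(self, index_100kb, genome_100kb):
        _, seq = genome_100kb
        read = ReadRecord("p", seq[40_000:40_100], "I" * 100)
        rec = align_single(read, index_100kb, SCORING, QUAL)
        assert (rec.stage, rec.qualified, rec.pos, rec.cigar, rec.strand) == (
            "LOCAL", True, 40_000, "100M", "+",
        )

    def test_substituted_read_score_matches_oracle_window(
        self, index_100kb, genome_100kb, rng
    ):
        _, seq = genome_100kb
        pos = 23_000
        read_seq = _mutate(rng, seq[pos : pos + 100], 2)
        rec = align_single(ReadRecord("m", read_seq, "I" * 100),
                           index_100kb, SCORING, QUAL)
        assert rec.qualified
        window = seq[pos - 50 : pos + 150]
        assert rec.score == sw_score(read_seq, window, 1, -3, -5, -2)

    def test_nongenomic_read_is_unaligned(self, index_2kb, genome_2kb, rng):
        """A read the exhaustive whole-genome oracle certifies as below
        threshold on both strands must come out UNALIGNED."""
        _, seq = genome_2kb
        rng2 = np.random.default_rng(99)
        read_seq = _random_seq(rng2, 100)
        best = max(
            sw_score(read_seq, seq, 1, -3, -5, -2),
            sw_score(rc(read_seq), seq, 1, -3, -5, -2),
        )
        assert best < QUAL.min_score_fraction * 100  # oracle certificate
        assert sliding_edit_distance(read_seq, seq) > 10
        assert sliding_edit_distance(rc(read_seq), seq) > 10
        rec = align_single(ReadRecord("x", read_seq, "I" * 100),
                           index_2kb, SCORING, QUAL)
        assert rec.stage == "UNALIGNED"
        assert rec.pos is None and not rec.qualified

    def test_cigar_conserves_read_length(self, index_2kb, genome_2kb, rng):
        _, seq = genome_2kb
        for _ in range(30):
            pos = int(rng.integers(0, len(seq) - 80))
            read_seq = _mutate(rng, seq[pos : pos + 80], int(rng.integers(0, 10)))
            rec = align_single(ReadRecord("f", read_seq, "I" * 80),
                               index_2kb, SCORING, QUAL)
            if rec.stage == "UNALIGNED":
                continue
            consumed = 0
            num = ""
            for ch in rec.cigar:
                if ch.isdigit():
                    num += ch
                else:
                    if ch in "MIS":
                        consumed += int(num)
                    num = ""
            assert consumed == 80

    def test_pipeline_is_deterministic(self, index_2kb, genome_2kb, rng):
        _, seq = genome_2kb
        read = ReadRecord("d", _mutate(rng, seq[111:191], 3), "I" * 80)
        recs = [align_single(read, index_2kb, SCORING, QUAL) for _ in range(2)]
        assert recs[0] == recs[1]

    def test_raising_score_threshold_is_monotone(self, index_2kb, genome_2kb, rng):
        """A stricter min_score_fraction can only lose alignments."""
        _, seq = genome_2kb
        strict = QualificationParams(min_score_fraction=0.8)
        for _ in range(20):
            pos = int(rng.integers(0, len(seq) - 80))
            read_seq = _mutate(rng, seq[pos : pos + 80], int(rng.integers(0, 20)))
            read = ReadRecord("m", read_seq, "I" * 80)
            lax_rec = align_single(read, index_2kb, SCORING, QUAL)
            strict_rec = align_single(read, index_2kb, SCORING, strict)
            if lax_rec.stage == "UNALIGNED":
                assert strict_rec.stage == "UNALIGNED" or \
                    strict_rec.stage in ("SEMIGLOBAL", "KMER_SEMIGLOBAL")


class TestPairSeeds:
    def _seed(self, pos, strand, score, offset=0):
        return Seed(read_offset=offset, genome_pos=pos, length=20, kind="MEM",
                    strand=strand, rank_score=score)

    def test_single_compatible_pair(self):
        s1 = self._seed(1000, "+", 90)
        s2 = self._seed(1200, "-", 80)
        pairs = pair_seeds([s1], [s2], QUAL, 100, 100)
        assert len(pairs) == 1
        assert pairs[0].implied_insert == 300
        assert pairs[0].pair_weight == 170

    def test_out_of_range_insert_yields_nothing(self):
        s1 = self._seed(1000, "+", 90)
        s2 = self._seed(1900, "-", 80)
        assert pair_seeds([s1], [s2], QUAL, 100, 100) == []

    def test_same_strand_yields_nothing(self):
        s1 = self._seed(1000, "+", 90)
        s2 = self._seed(1200, "+", 80)
        assert pair_seeds([s1], [s2], QUAL, 100, 100) == []

    def test_matches_brute_force_over_all_combinations(self, rng):
        mid = (QUAL.insert_min + QUAL.insert_max) / 2
        for _ in range(20):
            set1 = [self._seed(int(rng.integers(0, 3000)),
                               "+" if rng.random() < 0.5 else "-",
                               int(rng.integers(0, 100))) for _ in range(8)]
            set2 = [self._seed(int(rng.integers(0, 3000)),
                               "+" if rng.random() < 0.5 else "-",
                               int(rng.integers(0, 100))) for _ in range(8)]
            got = [
                (p.seed1.genome_pos, p.seed2.genome_pos, p.pair_weight,
                 p.implied_insert)
                for p in pair_seeds(set1, set2, QUAL, 100, 100)
            ]
            expected = []
            for a in set1:
                for b in set2:
                    if a.strand == b.strand:
                        continue
                    fwd, rev = (a, b) if a.strand == "+" else (b, a)
                    if fwd.genome_pos > rev.genome_pos:
                        continue
                    left = min(a.genome_pos, b.genome_pos)
                    right = max(a.genome_pos + 100, b.genome_pos + 100)
                    ins = right - left
                    if QUAL.insert_min <= ins <= QUAL.insert_max:
                        expected.append(
                            (a.genome_pos, b.genome_pos,
                             a.rank_score + b.rank_score, ins)
                        )
            expected.sort(key=lambda t: (-t[2], abs(t[3] - mid), t[0], t[1]))
            assert got == expected


class TestRescueMate:
    def test_planted_mate_recovered(self, index_100kb, genome_100kb):
        _, seq = genome_100kb
        pos = 60_000
        anchor = align_single(ReadRecord("a", seq[pos : pos + 100], "I" * 100),
                              index_100kb, SCORING, QUAL)
        mate = ReadRecord("a", rc(seq[pos + 200 : pos + 300]), "I" * 100)
        rec = rescue_mate(anchor, mate, index_100kb, SCORING, QUAL)
        assert (rec.stage, rec.qualified, rec.pos, rec.strand) == (
            "MATE_RESCUE", True, pos + 200, "-",
        )

    def test_equals_sliding_oracle_over_the_window(self, index_100kb,
                                                   genome_100kb, rng):
        pytest.importorskip("edlib")
        _, seq = genome_100kb
        pos = 30_000
        anchor = align_single(ReadRecord("a", seq[pos : pos + 100], "I" * 100),
                              index_100kb, SCORING, QUAL)
        mate_seq = _mutate(rng, rc(seq[pos + 250 : pos + 350]), 8)
        rec = rescue_mate(anchor, ReadRecord("a", mate_seq, "I" * 100),
                          index_100kb, SCORING, QUAL)
        window = seq[pos + QUAL.insert_min - 100 : pos + QUAL.insert_max]
        assert rec.edits == sliding_edit_distance(rc(mate_seq), window)

    def test_window_clipped_past_reference_end(self, index_2kb, genome_2kb):
        _, seq = genome_2kb
        # anchor near the end: the implied mate window lies beyond the genome
        anchor = align_single(ReadRecord("e", seq[1900:1980], "I" * 80),
                              index_2kb, SCORING, QUAL)
        assert anchor.qualified
        mate = ReadRecord("e", "ACGT" * 25, "I" * 100)
        rec = rescue_mate(anchor, mate, index_2kb, SCORING,
                          QualificationParams(insert_min=400, insert_max=500))
        assert rec.stage in ("MATE_RESCUE", "UNALIGNED")
        if anchor.g_start + 400 - 100 >= len(seq):
            assert rec.stage == "UNALIGNED"


class TestAlignPaired:
    def test_planted_fr_pair_is_proper(self, index_100kb, genome_100kb):
        _, seq = genome_100kb
        pos, insert = 45_000, 300
        r1 = ReadRecord("pp", seq[pos : pos + 100], "I" * 100)
        r2 = ReadRecord("pp", rc(seq[pos + insert - 100 : pos + insert]), "I" * 100)
        a1, a2 = align_paired(r1, r2, index_100kb, SCORING, QUAL)
        assert a1.qualified and a2.qualified
        assert a1.flag & 0x2 and a2.flag & 0x2  # proper pair
        assert (a1.pos, a2.pos) == (pos, pos + insert - 100)
        assert a1.tlen == insert and a2.tlen == -insert

    def test_corrupted_mate_recovered_by_rescue(self, index_100kb,
                                                genome_100kb, rng):
        _, seq = genome_100kb
        pos, insert = 52_000, 300
        clean = seq[pos : pos + 100]
        corrupt = _mutate(rng, rc(seq[pos + insert - 100 : pos + insert]), 20)
        a1, a2 = align_paired(
            ReadRecord("cm", clean, "I" * 100),
            ReadRecord("cm", corrupt, "I" * 100),
            index_100kb, SCORING, QUAL,
        )
        assert a1.qualified and a1.pos == pos
        assert a2.stage == "MATE_RESCUE"
        assert abs(a2.pos - (pos + insert - 100)) <= 5

    def test_nongenomic_pair_is_unaligned(self, index_2kb):
        rng2 = np.random.default_rng(77)
        r1 = ReadRecord("nn", _random_seq(rng2, 100), "I" * 100)
        r2 = ReadRecord("nn", _random_seq(rng2, 100), "I" * 100)
        a1, a2 = align_paired(r1, r2, index_2kb, SCORING, QUAL)
        assert a1.stage == "UNALIGNED" and a2.stage == "UNALIGNED"
        assert a1.flag & 0x4 and a2.flag & 0x8
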