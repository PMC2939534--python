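"""Seed-and-extend aligner: index, extension, search, and the brute-force
gap-free oracle it must never beat."""

import numpy as np
import pytest

from tagscout import (
    AlignParams,
    ReadKey,
    SequenceRecord,
    ValidationError,
    align_read,
    build_index,
    extend_seed,
    gapfree_local_oracle,
    reverse_complement,
)
from tagscout.seedalign import rescore
from tagscout.simdata import random_sequence

P = AlignParams()


def rand_seq(n, seed):
    return random_sequence(n, np.random.default_rng(seed))


class TestBuildIndex:
    def test_enumerates_all_windows(self):
        idx = build_index(SequenceRecord("q", "ACGTACGT"), 4)
        assert idx == {"ACGT": [0, 4], "CGTA": [1], "GTAC": [2], "TACG": [3]}

    def test_kmers_containing_n_are_excluded(self):
        assert build_index(SequenceRecord("q", "ACNTA"), 3) == {}

    def test_query_length_cap(self):
        long = SequenceRecord("q", "A" * 5001)
        with pytest.raises(ValidationError, match="5000"):
            build_index(long, 12)


class TestExtendSeed:
    def test_exact_substring(self):
        query = rand_seq(200, 0)
        read = query[10:46]
        got = extend_seed(query, read, 20, 10, P)
        q_start, q_end, r_start, r_end, score, matches, mismatches = got
        assert (q_start, q_end, r_start, r_end) == (10, 46, 0, 36)
        assert (score, matches, mismatches) == (36, 36, 0)

    def test_planted_mismatches_hand_scored(self):
        query = rand_seq(200, 1)
        read = list(query[:30])
        for off in (5, 20):
            read[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[off]]
        read = "".join(read)
        got = extend_seed(query, read, 6, 6, P)  # clean 12-mer at offsets 6..17
        q_start, q_end, _, _, score, matches, mismatches = got
        assert (q_start, q_end) == (0, 30)
        assert (matches, mismatches) == (28, 2)
        assert score == 28 * 1 + 2 * (-2) == 24
        assert matches / (q_end - q_start) == pytest.approx(28 / 30)

    def test_xdrop_stops_at_random_flank(self):
        rng = np.random.default_rng(7)
        query = random_sequence(200, rng)
        read = query[50:65] + random_sequence(15, rng)  # left half matches
        got = extend_seed(query, read, 50, 0, P)
        if got is not None:
            q_start, q_end, *_ = got
            # reported interval must not stretch deep into the random block
            assert q_end <= 65 + 5
            score = got[4]
            assert score <= gapfree_local_oracle(query, read, P)


class TestAlignRead:
    def test_duplicated_region_two_hits(self):
        core = rand_seq(36, 2)
        query = SequenceRecord("q", core + rand_seq(14, 3) + core + rand_seq(14, 4))
        idx = build_index(query, P.k)
        hits = align_read(SequenceRecord("r", core), idx, query, P)
        exact = [h for h in hits if h.matches == 36]
        assert [h.q_start for h in exact] == [0, 50]
        assert all(h.identity == 1.0 for h in exact)

    def test_minus_strand_hit(self):
        query = SequenceRecord("q", rand_seq(200, 5))
        read = SequenceRecord("r", reverse_complement(query.residues[100:136]))
        hits = align_read(read, build_index(query, P.k), query, P)
        assert len(hits) == 1
        h = hits[0]
        assert (h.q_start, h.q_end, h.strand) == (100, 136, "-")
        assert (h.r_start, h.r_end) == (0, 36)

    def test_random_reads_do_not_hit_unrelated_query(self):
        query = SequenceRecord("q", rand_seq(1000, 10))
        idx = build_index(query, P.k)
        rng = np.random.default_rng(1)
        n_hits = 0
        for _ in range(100):
            read = SequenceRecord("r", random_sequence(36, rng))
            n_hits += len(align_read(read, idx, query, P))
        assert n_hits == 0

    def test_sorted_best_first_and_deterministic(self):
        core = rand_seq(36, 2)
        query = SequenceRecord("q", core + rand_seq(14, 3) + core + rand_seq(14, 4))
        idx = build_index(query, P.k)
        read = SequenceRecord("r", core)
        h1 = align_read(read, idx, query, P)
        h2 = align_read(read, idx, query, P)
        assert h1 == h2
        scores = [h.score for h in h1]
        assert scores == sorted(scores, reverse=True)

    def test_strand_symmetry(self):
        query = SequenceRecord("q", rand_seq(300, 11))
        idx = build_index(query, P.k)
        rng = np.random.default_rng(12)
        for start in (0, 57, 133, 264 - 36):
            read = SequenceRecord("r", query.residues[start : start + 36])
            fwd = align_read(read, idx, query, P)
            rc = align_read(SequenceRecord("r", reverse_complement(read.residues)), idx, query, P)
            flip = {"+": "-", "-": "+"}
            assert {
                (h.q_start, h.q_end, flip[h.strand], 36 - h.r_end, 36 - h.r_start, h.score)
                for h in fwd
            } == {(h.q_start, h.q_end, h.strand, h.r_start, h.r_end, h.score) for h in rc}

    def test_score_recomputation_exact(self):
        query = SequenceRecord("q", rand_seq(400, 21))
        idx = build_index(query, P.k)
        rng = np.random.default_rng(22)
        for _ in range(30):
            start = int(rng.integers(0, 400 - 36))
            read_s = list(query.residues[start : start + 36])
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(0, 36))
                read_s[pos] = "ACGT"[int(rng.integers(0, 4))]
            seq = "".join(read_s)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            read = SequenceRecord("r", seq)
            for hit in align_read(read, idx, query, P):
                m, x, s = rescore(hit, query, read, P)
                assert (m, x, s) == (hit.matches, hit.mismatches, hit.score)
                assert hit.identity == m / hit.aligned_len
                assert hit.q_end - hit.q_start == hit.r_end - hit.r_start


class TestOracle:
    def test_identical_sequences(self):
        s = rand_seq(10, 30)
        assert gapfree_local_oracle(s, s, P) == 10

    def test_single_base_best(self):
        assert gapfree_local_oracle("ACGT", "TTTT", P) == 1

    def test_align_never_exceeds_oracle(self):
        rng = np.random.default_rng(40)
        query = SequenceRecord("q", random_sequence(200, rng))
        idx = build_index(query, P.k)
        for _ in range(50):
            start = int(rng.integers(0, 200 - 36))
            read_s = list(query.residues[start : start + 36])
            for _ in range(int(rng.integers(0, 4))):
                pos = int(rng.integers(0, 36))
                read_s[pos] = "ACGT"[int(rng.integers(0, 4))]
            read = SequenceRecord("r", "".join(read_s))
            hits = align_read(read, idx, query, P)
            best = hits[0].score if hits else 0
            assert best <= gapfree_local_oracle(query.residues, read.residues, P)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            AlignParams(k=4)
        with pytest.raises(ValidationError):
            AlignParams(mismatch_score=1)
        with pytest.raises(ValidationError):
            AlignParams(min_aligned_len=5)
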