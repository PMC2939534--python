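"""Pair geometry: concordance classification, mate envelopes, insert-model
estimation, and the Table-style tallies."""

import numpy as np
import pytest

from tagscout import (
    InsertModel,
    PairedReadLibrary,
    ReadSimSpec,
    SequenceRecord,
    ValidationError,
    classify,
    estimate_insert_model,
    group_by_fragment,
    infer_mate_envelope,
    simulate_pairs,
    tally,
)
from tagscout.pairing import (
    BOTH_CONCORDANT,
    BOTH_DISCORDANT,
    SINGLE_END,
    UNMAPPED,
    PairHit,
)
from tagscout.simdata import random_sequence

from conftest import make_hit


class TestClassify:
    def test_concordant_within_bounds(self, insert_900_1100):
        h1 = make_hit(100, 136, "+", read_len=36, mate=1)
        h2 = make_hit(1044, 1080, "-", read_len=36, fragment="f1", mate=2)
        # implied outer length 1080 - 100 = 980
        assert classify(h1, h2, insert_900_1100) == BOTH_CONCORDANT

    def test_too_far_apart_discordant(self, insert_900_1100):
        h1 = make_hit(100, 136, "+", read_len=36, mate=1)
        h2 = make_hit(2000, 2036, "-", read_len=36, mate=2)
        assert classify(h1, h2, insert_900_1100) == BOTH_DISCORDANT

    def test_same_strand_discordant_regardless_of_distance(self, insert_900_1100):
        h1 = make_hit(100, 136, "+", read_len=36, mate=1)
        h2 = make_hit(1044, 1080, "+", read_len=36, mate=2)
        assert classify(h1, h2, insert_900_1100) == BOTH_DISCORDANT

    def test_wrong_order_discordant(self, insert_900_1100):
        h1 = make_hit(1044, 1080, "+", read_len=36, mate=1)
        h2 = make_hit(100, 136, "-", read_len=36, mate=2)
        assert classify(h1, h2, insert_900_1100) == BOTH_DISCORDANT

    def test_symmetric_in_mate_order(self, insert_900_1100):
        h1 = make_hit(100, 136, "+", read_len=36, mate=1)
        h2 = make_hit(1044, 1080, "-", read_len=36, mate=2)
        assert classify(h1, h2, insert_900_1100) == classify(h2, h1, insert_900_1100)

    def test_projection_uses_full_read(self, insert_900_1100):
        # partially aligned plus mate: alignment [110,136) but read starts 10
        # bases earlier, so the projected start is 100 and L is still 980
        h1 = make_hit(110, 136, "+", read_len=36, mate=1, r_start=10, r_end=36)
        h2 = make_hit(1044, 1080, "-", read_len=36, mate=2)
        assert h1.projected_interval() == (100, 136)
        assert classify(h1, h2, insert_900_1100) == BOTH_CONCORDANT


class TestMateEnvelope:
    def test_plus_anchor_envelope(self, insert_900_1100):
        hit = make_hit(100, 136, "+", read_len=36)
        pl = infer_mate_envelope(hit, 36, insert_900_1100)
        assert (pl.envelope_start, pl.envelope_end) == (964, 1200)
        assert pl.strand == "-"
        assert pl.envelope_end - pl.envelope_start == (1100 - 900) + 36

    def test_minus_anchor_envelope_upstream_of_query(self):
        model = InsertModel(mean=1000, sd=25, L_min=950, L_max=1050)
        hit = make_hit(100, 200, "-", read_len=100)
        pl = infer_mate_envelope(hit, 100, model)
        assert (pl.envelope_start, pl.envelope_end) == (-850, -650)
        assert pl.strand == "+"

    def test_degenerate_insert_envelope_width_is_read_len(self):
        model = InsertModel(mean=1000, sd=0, L_min=1000, L_max=1000)
        hit = make_hit(0, 36, "+", read_len=36)
        pl = infer_mate_envelope(hit, 36, model)
        assert pl.envelope_end - pl.envelope_start == 36


def tiny_library(fragments):
    lib = PairedReadLibrary(name="lib")
    for frag in fragments:
        lib.fragments[frag] = (
            SequenceRecord(f"{frag}/1", "ACGTACGT"),
            SequenceRecord(f"{frag}/2", "ACGTACGT"),
        )
    return lib


class TestGroupByFragment:
    def test_categories(self, insert_900_1100):
        lib = tiny_library(["f1", "f2"])
        hits = [
            make_hit(100, 136, "+", read_len=36, fragment="f1", mate=1),
            make_hit(1044, 1080, "-", read_len=36, fragment="f1", mate=2),
            make_hit(50, 86, "+", read_len=36, fragment="f2", mate=1),
        ]
        out = group_by_fragment(hits, lib, insert_900_1100)
        cats = {p.fragment_id: p.category for p in out}
        assert cats["f1"].startswith("both_")
        assert cats["f2"] == SINGLE_END
        assert next(p for p in out if p.fragment_id == "f2").placement is not None

    def test_no_hits_empty(self, insert_900_1100):
        assert group_by_fragment([], tiny_library(["f1"]), insert_900_1100) == []

    def test_best_hit_tie_break_smaller_q_start(self, insert_900_1100):
        lib = tiny_library(["f1"])
        hits = [
            make_hit(500, 530, "+", read_len=30, fragment="f1", mate=1, score=30, matches=30),
            make_hit(100, 130, "+", read_len=30, fragment="f1", mate=1, score=30, matches=30),
            make_hit(300, 330, "+", read_len=30, fragment="f1", mate=1, score=24, matches=28),
        ]
        (ph,) = group_by_fragment(hits, lib, insert_900_1100)
        assert ph.hit1.q_start == 100

    def test_unknown_read_rejected(self, insert_900_1100):
        with pytest.raises(ValidationError, match="unknown"):
            group_by_fragment(
                [make_hit(0, 30, fragment="ghost")], tiny_library(["f1"]), insert_900_1100
            )

    def test_partition_invariant(self, insert_900_1100):
        lib = tiny_library(["f1", "f2", "f3", "f4"])
        hits = [
            make_hit(100, 136, "+", read_len=36, fragment="f1", mate=1),
            make_hit(1044, 1080, "-", read_len=36, fragment="f1", mate=2),
            make_hit(50, 86, "+", read_len=36, fragment="f2", mate=1),
        ]
        out = group_by_fragment(hits, lib, insert_900_1100, include_unmapped=True)
        by_cat = {}
        for p in out:
            by_cat[p.category] = by_cat.get(p.category, 0) + 1
        n_both = by_cat.get(BOTH_CONCORDANT, 0) + by_cat.get(BOTH_DISCORDANT, 0)
        assert n_both + by_cat.get(SINGLE_END, 0) + by_cat.get(UNMAPPED, 0) == lib.n_fragments


class TestEstimateInsertModel:
    def fallback(self):
        return InsertModel(mean=500, sd=100, L_min=300, L_max=700)

    def pairs_with_L(self, Ls, read_len=50):
        out = []
        for i, L in enumerate(Ls):
            h1 = make_hit(0, read_len, "+", read_len=read_len, fragment=f"f{i}", mate=1)
            h2 = make_hit(L - read_len, L, "-", read_len=read_len, fragment=f"f{i}", mate=2)
            out.append(PairHit(f"f{i}", h1, h2, BOTH_CONCORDANT))
        return out

    def test_exact_lengths(self):
        model = estimate_insert_model(self.pairs_with_L([1000] * 100), self.fallback())
        assert model.mean == 1000 and model.sd == 0
        assert model.L_min == model.L_max == 1000

    def test_too_few_pairs_returns_fallback(self):
        fb = self.fallback()
        assert estimate_insert_model(self.pairs_with_L([500] * 10), fb) is fb

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(123)
        Ls = []
        while len(Ls) < 500:
            L = int(round(rng.normal(500, 30)))
            if 400 <= L <= 600:
                Ls.append(L)
        model = estimate_insert_model(self.pairs_with_L(Ls), self.fallback())
        assert abs(model.mean - 500) <= 5
        assert abs(model.sd - 30) <= 6


class TestTally:
    def test_mixed_categories(self, insert_900_1100):
        phs = [
            PairHit("f1", make_hit(0, 36), make_hit(900, 936, "-"), BOTH_CONCORDANT),
            PairHit("f2", make_hit(0, 36), None, SINGLE_END),
            PairHit("f3", None, None, UNMAPPED),
        ]
        rep = tally(phs, "lib")
        assert (rep.n_read_pairs, rep.n_single_reads, rep.n_total_hits) == (1, 1, 3)

    def test_empty(self):
        rep = tally([], "no_ortholog_lib")
        assert (rep.n_read_pairs, rep.n_single_reads, rep.n_total_hits) == (0, 0, 0)

    def test_disjoint_counts_on_large_mixed_fixture(self):
        phs = [
            PairHit(f"p{i}", make_hit(0, 36, fragment=f"p{i}"), make_hit(900, 936, "-", fragment=f"p{i}", mate=2), BOTH_CONCORDANT)
            for i in range(45)
        ] + [
            PairHit(f"s{i}", make_hit(0, 36, fragment=f"s{i}"), None, SINGLE_END)
            for i in range(332)
        ]
        rep = tally(phs, "close_relative")
        assert (rep.n_read_pairs, rep.n_single_reads, rep.n_total_hits) == (45, 332, 422)


class TestEnvelopeSoundness:
    """Simulated fragments with hard-truncated lengths: the true unmapped-mate
    interval always lies inside the inferred envelope."""

    def containment_rate(self, model, sim_bounds, n=1000):
        genome = SequenceRecord("g", random_sequence(8000, np.random.default_rng(9)))
        spec = ReadSimSpec(
            coverage=2 * n * 50 / 8000,
            read_len=50,
            insert=sim_bounds,
            error_rate=0.0,
            seed=11,
        )
        lib, truth = simulate_pairs(genome, spec)
        ok = total = 0
        for t in truth:
            (s1, e1, st1), (s2, e2, st2) = t.intervals(50)
            # anchor mate 1, infer mate 2
            h1 = make_hit(s1, e1, "+", read_len=50, fragment=t.fragment_id, mate=1)
            pl = infer_mate_envelope(h1, 50, model)
            total += 1
            if pl.envelope_start <= s2 and e2 <= pl.envelope_end and pl.strand == st2:
                ok += 1
            assert pl.envelope_end - pl.envelope_start == (model.L_max - model.L_min) + 50
            # anchor mate 2, infer mate 1
            h2 = make_hit(s2, e2, "-", read_len=50, fragment=t.fragment_id, mate=2)
            pl = infer_mate_envelope(h2, 50, model)
            total += 1
            if pl.envelope_start <= s1 and e1 <= pl.envelope_end and pl.strand == st1:
                ok += 1
        return ok / total

    def test_hard_truncation_always_contained(self):
        model = InsertModel(mean=500, sd=30, L_min=400, L_max=600)
        assert self.containment_rate(model, model, n=1000) == 1.0

    def test_two_sigma_bounds_contain_at_least_93_percent(self):
        draw = InsertModel(mean=500, sd=30, L_min=350, L_max=650)  # ~ +-5 sd: near-Normal
        model = InsertModel(mean=500, sd=30, L_min=440, L_max=560)  # mean +- 2 sd
        rate = self.containment_rate(model, draw, n=1000)
        assert rate >= 0.93
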