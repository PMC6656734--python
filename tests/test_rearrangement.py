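"""Forward event operators, scenario inference, tdrl distance."""

import itertools

import numpy as np
import pytest

from conftest import make_order, random_signed_order
from oracle_utils import bfs_tdrl_distances, single_event_types

from mitoarch.gene_orders import GeneOrder
from mitoarch.rearrangement import (
    RearrangementEvent,
    Scenario,
    apply_event,
    apply_scenario,
    event_count_to_reference,
    infer_scenario,
    tdrl_distance_permutation,
    tdrl_min_count,
)
from mitoarch.simulate import _sample_event


class TestApplyEvent:
    def test_reversal_flips_order_and_signs(self):
        o = make_order("a b c d")
        out = apply_event(o, RearrangementEvent("r", 1, 3))
        assert out.tokens == (("a", 1), ("c", -1), ("b", -1), ("d", 1))

    def test_transposition_moves_segment(self):
        o = make_order("a b c d e")
        # move (b,c) after d: remove [1:3], insert at position 2 of (a,d,e)
        out = apply_event(o, RearrangementEvent("T", 1, 3, insert_at=2))
        assert out.tokens == (("a", 1), ("d", 1), ("b", 1), ("c", 1), ("e", 1))

    def test_tdrl_keeps_bipartition_in_tandem_order(self):
        o = make_order("a b c d e")
        # window (b,c,d), keep {b,d} first and {c} second
        out = apply_event(o, RearrangementEvent("tdrl", 1, 4,
                                                keep_first=frozenset({0, 2})))
        assert out.tokens == (("a", 1), ("b", 1), ("d", 1), ("c", 1), ("e", 1))

    def test_duplication_and_deletion_are_inverse(self):
        o = make_order("a b c d")
        dup = apply_event(o, RearrangementEvent("d", 1, 3))
        assert [g for g, _ in dup.tokens] == ["a", "b", "c", "b", "c", "d"]
        back = apply_event(dup, RearrangementEvent("x", 3, 5))
        assert back.tokens == o.tokens

    def test_out_of_range_segment_rejected(self):
        with pytest.raises(ValueError):
            apply_event(make_order("a b c"), RearrangementEvent("r", 1, 7))


class TestSingleEventInference:
    def test_equal_orders_give_empty_scenario(self):
        o = make_order("a b c d e")
        scen = infer_scenario(o, GeneOrder("t2", o.tokens))
        assert scen.events == () and scen.complete

    def test_spec_reversal_example(self):
        src = make_order("a b c d e")
        tgt = make_order("a -c -b d e")
        scen = infer_scenario(src, tgt)
        assert len(scen.events) == 1 and scen.events[0].type == "r"
        assert scen.events[0].start == 1 and scen.events[0].end == 3

    def test_spec_tdrl_example(self):
        src = make_order("a b c d e")
        tgt = make_order("a c e b d")  # relative permutation (1,3,5,2,4)
        scen = infer_scenario(src, tgt)
        assert len(scen.events) == 1 and scen.events[0].type == "tdrl"
        assert apply_scenario(GeneOrder("t", src.tokens), scen.events).tokens == tgt.tokens

    def test_planted_single_events_recovered_consistently_with_oracle(self, rng):
        """Every planted r/T/rT event yields a 1-event scenario whose type the
        exhaustive single-event oracle confirms can explain the pair."""
        for trial in range(300):
            n = int(rng.integers(5, 11))
            src = random_signed_order(rng, n)
            ev = _sample_event(src, {"T": 1, "r": 1, "rT": 1}, rng, max_segment=4)
            tgt = apply_event(src, ev)
            scen = infer_scenario(src, tgt)
            assert scen.complete
            if src.tokens == tgt.tokens:
                assert scen.events == ()
                continue
            assert len(scen.events) == 1
            feasible = single_event_types(list(src.tokens), tgt.tokens)
            assert scen.events[0].type in feasible
            assert apply_event(src, scen.events[0]).tokens == tgt.tokens

    def test_preference_order_reversal_before_transposition(self, rng):
        # sign-flipping single-gene reversal must come out as r, never rT
        src = make_order("a b c d e")
        tgt = apply_event(src, RearrangementEvent("r", 2, 3))
        scen = infer_scenario(src, tgt)
        assert scen.events[0].type == "r"

    def test_gene_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            infer_scenario(make_order("a b c"), make_order("a b d"))


class TestTdrlDistance:
    def test_known_values(self):
        assert tdrl_distance_permutation((1, 2, 3, 4, 5)) == 0
        assert tdrl_distance_permutation((1, 3, 5, 2, 4)) == 1
        assert tdrl_distance_permutation((5, 4, 3, 2, 1)) == 3  # s=5

    def test_matches_bfs_oracle_up_to_n5(self):
        for n in (2, 3, 4, 5):
            oracle = bfs_tdrl_distances(n)
            for perm in itertools.permutations(range(1, n + 1)):
                assert tdrl_distance_permutation(perm) == oracle[perm], perm

    def test_gene_order_wrapper_agrees_with_scenario_construction(self, rng):
        letters = "abcdefg"
        for _ in range(50):
            n = int(rng.integers(4, 8))
            src = GeneOrder.from_tokens("s", [(letters[i], 1) for i in range(n)])
            perm = rng.permutation(n)
            tgt = GeneOrder.from_tokens("t", [(letters[int(p)], 1) for p in perm])
            k = tdrl_min_count(src, tgt)
            scen = infer_scenario(src, tgt)
            assert scen.complete
            # inference may use a cheaper single event; never more than the
            # tdrl optimum
            assert len(scen.events) <= max(k, 1)
            assert apply_scenario(GeneOrder("x", src.tokens), scen.events).tokens == tgt.tokens

    def test_mixed_signs_rejected(self):
        with pytest.raises(ValueError, match="infer_scenario"):
            tdrl_min_count(make_order("a b c d"), make_order("a -b c d"))


class TestScenarioSoundness:
    def test_random_multievent_scenarios_replay_exactly(self, rng, ground_pattern):
        weights = {"T": 1, "r": 1, "rT": 1, "tdrl": 1}
        for trial in range(150):
            n = int(rng.integers(6, 11))
            src = random_signed_order(rng, n)
            o = src
            for _ in range(int(rng.integers(1, 5))):
                ev = _sample_event(o, weights, rng, max_segment=4)
                if ev is not None:
                    o = apply_event(o, ev)
            scen = infer_scenario(src, o)
            if scen.complete:
                replay = apply_scenario(GeneOrder("x", src.tokens), scen.events)
                assert replay.tokens == o.tokens
            else:
                assert scen.breakpoints is not None and scen.breakpoints > 0

    def test_full_gene_complement_scenarios(self, rng, ground_pattern):
        weights = {"T": 1, "r": 1, "rT": 1, "tdrl": 1}
        for trial in range(30):
            o = ground_pattern
            for _ in range(3):
                ev = _sample_event(o, weights, rng, max_segment=6)
                o = apply_event(o, ev)
            scen = infer_scenario(ground_pattern, o)
            if scen.complete:
                got = apply_scenario(GeneOrder("x", ground_pattern.tokens), scen.events)
                assert got.tokens == o.tokens


class TestEventCountToReference:
    def test_zero_iff_equal(self, ground_pattern):
        assert event_count_to_reference(
            GeneOrder("t", ground_pattern.tokens), ground_pattern) == 0

    def test_one_planted_reversal_counts_one(self, ground_pattern, rng):
        tgt = apply_event(ground_pattern, RearrangementEvent("r", 4, 9))
        assert event_count_to_reference(tgt, ground_pattern) == 1

    def test_two_noninteracting_transpositions_count_two(self, ground_pattern):
        o = apply_event(ground_pattern, RearrangementEvent("T", 2, 4, insert_at=6))
        o = apply_event(o, RearrangementEvent("T", 20, 22, insert_at=25))
        count = event_count_to_reference(o, ground_pattern)
        assert count == 2
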