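"""Canonicalisation, pattern clustering, breakpoint distance, AMIGA."""

import itertools

import numpy as np
import pytest

from conftest import make_order, random_signed_order
from oracle_utils import naive_canonical

from mitoarch.gene_orders import (
    GeneOrder,
    amiga,
    breakpoint_distance,
    canonicalize,
    cluster_patterns,
    extract_gene_order,
    restrict_to_shared_genes,
)
from mitoarch.annotation_io import GeneFeature, MitogenomeRecord
from mitoarch.rearrangement import RearrangementEvent, apply_event


class TestCanonicalisation:
    def test_idempotent_and_rotation_reflection_invariant(self, rng):
        for trial in range(200):
            n = int(rng.integers(3, 9))
            o = random_signed_order(rng, n)
            toks = list(o.tokens)
            # arbitrary rotation
            k = int(rng.integers(n))
            rotated = toks[k:] + toks[:k]
            # reflection (other strand)
            reflected = [(g, -s) for g, s in reversed(toks)]
            assert canonicalize(rotated) == o.tokens
            assert canonicalize(reflected) == o.tokens
            assert canonicalize(list(o.tokens)) == o.tokens

    def test_matches_naive_canonicaliser(self, rng):
        for trial in range(100):
            n = int(rng.integers(3, 8))
            letters = [chr(ord("a") + i) for i in range(n)]
            toks = [(letters[int(p)], int(rng.choice([1, -1])))
                    for p in rng.permutation(n)]
            assert canonicalize(toks) == naive_canonical(toks)

    def test_anchor_reflection_rule(self):
        # cox1 on the minus strand: reverse the list, flip signs, re-rotate
        o = make_order("-cox1 -cox2 trnK")
        assert o.tokens == (("cox1", 1), ("trnK", -1), ("cox2", 1))


class TestExtraction:
    @staticmethod
    def _record(feats):
        features = [
            GeneFeature(token=t, kind="PCG" if not t.startswith("trn") else "tRNA",
                        strand=s, start=st, end=st + 100)
            for t, s, st in feats
        ]
        return MitogenomeRecord(taxon_id="tax", sequence="A" * 5000, features=features)

    def test_sorted_by_start_already_canonical(self):
        rec = self._record([("cox1", 1, 0), ("trnK", 1, 900), ("cox2", 1, 1000)])
        assert extract_gene_order(rec).tokens == (
            ("cox1", 1), ("trnK", 1), ("cox2", 1))

    def test_rotation_to_anchor(self):
        # file starts at trnK: rotation must bring cox1 to front
        rec = self._record([("trnK", 1, 0), ("cox2", 1, 200), ("cox1", 1, 400)])
        assert extract_gene_order(rec).tokens == (
            ("cox1", 1), ("trnK", 1), ("cox2", 1))

    def test_reflection_when_anchor_minus(self):
        rec = self._record([("cox1", -1, 0), ("cox2", -1, 200), ("trnK", 1, 400)])
        assert extract_gene_order(rec).tokens == (
            ("cox1", 1), ("trnK", -1), ("cox2", 1))

    def test_no_features_of_class_errors(self):
        rec = self._record([("cox1", 1, 0)])
        with pytest.raises(ValueError):
            extract_gene_order(rec, gene_classes=("rRNA",))


class TestSharedGeneRestriction:
    def test_unshared_gene_dropped(self):
        o1 = make_order("a b c d", "t1")
        o2 = make_order("a c d", "t2")
        out, report = restrict_to_shared_genes([o1, o2])
        assert out[0].tokens == out[1].tokens == (("a", 1), ("c", 1), ("d", 1))
        assert any("dropped unshared gene b" in line for line in report)

    def test_duplicate_collapsed_to_first_copy(self):
        o1 = make_order("a b b c", "t1")
        o2 = make_order("a b c", "t2")
        out, report = restrict_to_shared_genes([o1, o2])
        assert out[0].tokens == out[1].tokens == (("a", 1), ("b", 1), ("c", 1))
        assert any("duplicate" in line for line in report)

    def test_noop_when_all_shared(self):
        orders = [make_order("a b c d", "t1"), make_order("a c b d", "t2")]
        out, report = restrict_to_shared_genes(orders)
        assert [o.tokens for o in out] == [o.tokens for o in orders]
        assert report == []

    def test_too_few_shared_genes_errors(self):
        with pytest.raises(ValueError, match="incomparable"):
            restrict_to_shared_genes([make_order("a b", "t1"), make_order("a c", "t2")])


class TestPatternClustering:
    def test_rotations_cluster_together(self):
        orders = [make_order("a b c", "t1"), make_order("b c a", "t2"),
                  make_order("a c b", "t3")]
        pats = cluster_patterns(orders)
        assert sorted(p.count for p in pats) == [1, 2]

    def test_all_identical_one_pattern(self):
        orders = [make_order("a b c", f"t{i}") for i in range(5)]
        pats = cluster_patterns(orders)
        assert len(pats) == 1 and pats[0].count == 5

    def test_counts_partition_dataset(self, rng):
        orders = [random_signed_order(rng, 5, f"t{i}") for i in range(20)]
        pats = cluster_patterns(orders)
        assert sum(p.count for p in pats) == 20
        members = [m for p in pats for m in p.members]
        assert sorted(members) == sorted(o.taxon_id for o in orders)

    def test_ground_pattern_labelled_gr(self, ground_pattern):
        orders = [GeneOrder(f"t{i}", ground_pattern.tokens) for i in range(3)]
        orders.append(make_order(
            " ".join(("-" if s < 0 else "") + g
                     for g, s in reversed(ground_pattern.tokens[1:])) + " cox1", "t3"))
        pats = cluster_patterns(orders, prefix_map={"t0": "An", "t3": "An"})
        ids = {p.pattern_id for p in pats}
        assert "Gr" in ids

    def test_prefix_numbering_in_first_appearance_order(self):
        orders = [make_order("a b c", "t1"), make_order("a c b", "t2"),
                  make_order("b a -c", "t3")]
        pats = cluster_patterns(orders, prefix_map={"t1": "An", "t2": "An", "t3": "An"})
        assert [p.pattern_id for p in pats] == ["An1", "An2", "An3"]


class TestBreakpointDistance:
    def test_spec_examples(self):
        a = make_order("a b c d e")
        assert breakpoint_distance(a, a) == 0
        assert breakpoint_distance(a, make_order("a c b d e")) == 3
        assert breakpoint_distance(a, make_order("a -c -b d e")) == 2

    def test_is_a_metric_on_random_orders(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 8))
            x, y, z = (random_signed_order(rng, n) for _ in range(3))
            dxy = breakpoint_distance(x, y)
            assert dxy == breakpoint_distance(y, x)
            assert (dxy == 0) == (x.tokens == y.tokens)
            assert dxy <= breakpoint_distance(x, z) + breakpoint_distance(z, y)

    def test_single_events_change_known_numbers_of_adjacencies(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 10))
            o = random_signed_order(rng, n)
            i = int(rng.integers(1, n - 2))
            j = int(rng.integers(i + 1, n - 1))
            rev = apply_event(o, RearrangementEvent("r", i, j))
            assert breakpoint_distance(o, rev) <= 2
            k = int(rng.integers(1, n - (j - i)))
            if k != i:
                trans = apply_event(o, RearrangementEvent("T", i, j, insert_at=k))
                assert breakpoint_distance(o, trans) <= 3

    def test_differing_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="restrict_to_shared_genes"):
            breakpoint_distance(make_order("a b c"), make_order("a b d"))


class TestAmiga:
    def test_ratio_examples(self):
        orders = [make_order("a b c", "t1"), make_order("a b c", "t2"),
                  make_order("a c b", "t3"), make_order("b -a c", "t4")]
        pats = cluster_patterns(orders)
        vals = amiga(pats, 4)
        assert vals["t1"] == vals["t2"] == 0.5
        assert vals["t3"] == vals["t4"] == 0.25

    def test_all_identical_gives_one(self):
        pats = cluster_patterns([make_order("a b c", f"t{i}") for i in range(10)])
        assert set(amiga(pats, 10).values()) == {1.0}

    def test_mean_amiga_equals_sum_of_squared_pattern_fractions(self, rng):
        orders = [random_signed_order(rng, 4, f"t{i}") for i in range(12)]
        pats = cluster_patterns(orders)
        vals = amiga(pats, 12)
        mean = sum(vals.values()) / 12
        assert mean == pytest.approx(sum((p.count / 12) ** 2 for p in pats))
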