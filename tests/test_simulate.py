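"""Synthetic dataset generator: determinism, planted truth, composition targets."""

import numpy as np
import pytest

from mitoarch.annotation_io import read_genbank
from mitoarch.composition import (
    base_composition,
    codon_usage,
    rscu,
    strand_usage_skew,
    unassigned_fraction,
)
from mitoarch.gene_orders import extract_gene_order
from mitoarch.simulate import (
    CompositionTargets,
    SimulationConfig,
    evolve_orders,
    make_rate_table,
    simulate_dataset,
    simulate_tree,
    synthesize_record,
    tree_to_newick,
)


class TestSimulateTree:
    def test_same_seed_gives_byte_identical_newick(self):
        cfg = SimulationConfig(n_taxa=10, seed=42)
        t1 = tree_to_newick(simulate_tree(cfg))
        t2 = tree_to_newick(simulate_tree(cfg))
        assert t1 == t2

    def test_leaf_count_and_outgroup(self):
        cfg = SimulationConfig(n_taxa=3, seed=1)
        tree = simulate_tree(cfg)
        labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
        assert len(labels) == 4 and "outgroup" in labels

    def test_different_seeds_differ(self):
        a = tree_to_newick(simulate_tree(SimulationConfig(n_taxa=10, seed=1)))
        b = tree_to_newick(simulate_tree(SimulationConfig(n_taxa=10, seed=2)))
        assert a != b


class TestEvolveOrders:
    def test_zero_rate_keeps_root_order_everywhere(self, ground_pattern):
        cfg = SimulationConfig(n_taxa=8, seed=5, event_rate=0.0)
        tree = simulate_tree(cfg)
        leaf_orders, truth = evolve_orders(tree, cfg)
        assert truth.n_events == 0
        assert all(o.tokens == ground_pattern.tokens for o in leaf_orders.values())

    def test_truth_replays_to_every_leaf(self, ground_pattern):
        from mitoarch.gene_orders import GeneOrder
        from mitoarch.rearrangement import apply_scenario
        from mitoarch.simulate import node_name

        cfg = SimulationConfig(n_taxa=10, seed=9, event_rate=0.5)
        tree = simulate_tree(cfg)
        leaf_orders, truth = evolve_orders(tree, cfg)
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            parent = truth.node_orders[node_name(node.parent_node)]
            got = apply_scenario(GeneOrder("x", parent.tokens),
                                 truth.branch_events[node_name(node)])
            assert got.tokens == truth.node_orders[node_name(node)].tokens

    def test_poisson_event_totals_match_rate(self):
        totals, expect = [], []
        for seed in range(40):
            cfg = SimulationConfig(n_taxa=10, seed=seed, event_rate=0.4)
            tree = simulate_tree(cfg)
            _, truth = evolve_orders(tree, cfg)
            totals.append(truth.n_events)
            expect.append(0.4 * sum(e.length or 0 for e in tree.preorder_edge_iter()
                                    if e.length))
        mean_obs = np.mean(totals)
        mean_exp = np.mean(expect)
        se = np.sqrt(mean_exp / len(totals))
        assert abs(mean_obs - mean_exp) < 3 * se + 0.5

    def test_duplicates_only_deleted_never_last_copy(self, ground_pattern):
        from collections import Counter

        cfg = SimulationConfig(n_taxa=12, seed=31, event_rate=1.0,
                               event_weights={"d": 0.5, "x": 0.5})
        tree = simulate_tree(cfg)
        leaf_orders, _ = evolve_orders(tree, cfg)
        base = set(g for g, _ in ground_pattern.tokens)
        for o in leaf_orders.values():
            counts = Counter(g for g, _ in o.tokens)
            assert set(counts) == base  # no gene ever fully lost


class TestSynthesizeRecords:
    def test_composition_targets_realised(self, ground_pattern, rng):
        targets = CompositionTargets(at_percent=70.0, at_skew=0.1, gc_skew=-0.2,
                                     ur_percent=12.0)
        rec = synthesize_record(ground_pattern, targets, rng)
        at, ats, gcs = base_composition(rec)
        assert at == pytest.approx(70.0, abs=2.0)
        assert ats == pytest.approx(0.1, abs=0.04)
        assert unassigned_fraction(rec) == pytest.approx(12.0, abs=0.5)
        assert 14000 < rec.length < 19000

    def test_gap_run_excluded_from_composition(self, ground_pattern, rng):
        targets = CompositionTargets(at_percent=80.0)
        rec = synthesize_record(ground_pattern, targets, rng, gap_length=300)
        assert "N" * 300 in rec.sequence
        at, _, _ = base_composition(rec)
        assert at == pytest.approx(80.0, abs=2.0)

    def test_su_skew_follows_planted_strands(self, ground_pattern, rng):
        rec = synthesize_record(ground_pattern, CompositionTargets(), rng)
        su = strand_usage_skew(rec)
        plus = sum(f.end - f.start for f in rec.features if f.strand > 0)
        minus = sum(f.end - f.start for f in rec.features if f.strand < 0)
        assert su == pytest.approx((plus - minus) / (plus + minus))

    def test_codon_bias_detectable_in_rscu(self, ground_pattern, rng):
        # AT-rich base sampling makes T/A-ending codons overrepresented
        targets = CompositionTargets(at_percent=75.0)
        rec = synthesize_record(ground_pattern, targets, rng)
        vals = rscu(codon_usage(rec))
        spread = max(vals.values()) - min(vals.values())
        assert spread > 0.5

    def test_roundtrip_genbank_preserves_planted_order(self, tmp_path, ground_pattern):
        cfg = SimulationConfig(n_taxa=6, seed=77, event_rate=0.3)
        sim = simulate_dataset(cfg, out_dir=tmp_path)
        for taxon, planted in sim.leaf_orders.items():
            rec = read_genbank(tmp_path / "genbank" / f"{taxon}.gb")
            assert extract_gene_order(rec).tokens == planted.tokens


class TestRateTable:
    def test_null_mode_uncorrelated_by_construction(self):
        cfg = SimulationConfig(n_taxa=10, seed=3, rate_mode="null")
        tree = simulate_tree(cfg)
        _, truth = evolve_orders(tree, cfg)
        rates = make_rate_table(tree, truth, cfg)
        assert set(rates.columns) == {"taxon_id", "rate"}
        assert len(rates) == 11  # ingroup + outgroup

    def test_linked_mode_tracks_event_counts(self):
        from scipy import stats

        cfg = SimulationConfig(n_taxa=60, seed=8, event_rate=0.6,
                               rate_mode="linked", rate_slope=0.5,
                               rate_noise_sd=0.05)
        tree = simulate_tree(cfg)
        _, truth = evolve_orders(tree, cfg)
        rates = make_rate_table(tree, truth, cfg).set_index("taxon_id")
        counts = [truth.path_event_counts[t] for t in rates.index]
        rho = stats.spearmanr(counts, rates["rate"]).statistic
        assert rho > 0.6

    def test_same_seed_identical_table(self):
        cfg = SimulationConfig(n_taxa=10, seed=13)
        tree = simulate_tree(cfg)
        _, truth = evolve_orders(tree, cfg)
        r1 = make_rate_table(tree, truth, cfg)
        tree2 = simulate_tree(cfg)
        _, truth2 = evolve_orders(tree2, cfg)
        r2 = make_rate_table(tree2, truth2, cfg)
        assert r1.equals(r2)


class TestFullDatasetDeterminism:
    def test_identical_outputs_for_identical_config(self, tmp_path):
        cfg = SimulationConfig(n_taxa=5, seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg, out_dir=d1)
        simulate_dataset(cfg, out_dir=d2)
        for rel in ["tree.nwk", "truth.json", "rates.tsv"]:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        for gb in sorted((d1 / "genbank").glob("*.gb")):
            assert gb.read_bytes() == (d2 / "genbank" / gb.name).read_bytes()
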