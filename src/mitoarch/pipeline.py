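"""End-to-end orchestration: simulate/read -> orders -> patterns -> ancestral
-> composition -> index -> PCA -> correlations, with a fixed output layout.

Stages communicate only through their documented output files, so real and
synthetic inputs mix freely. Re-running with unchanged inputs reproduces
byte-identical non-log outputs (writers embed no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .ancestral import edge_event_summary, reconstruct
from .annotation_io import (
    read_genbank_dir,
    write_gene_orders_tsv,
    write_json,
    write_patterns_tsv,
)
from .composition import codon_long_table, composition_profile, profiles_table
from .gene_orders import (
    GeneOrder,
    amiga,
    canonicalize,
    cluster_patterns,
    extract_gene_order,
    load_ground_pattern,
    restrict_to_shared_genes,
)
from .hermes import build_variables, fit_hermes, tree_distances
from .multivariate import mgo_rate_correlation, pca_correlation
from .simulate import CompositionTargets, SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: Path
    input_dir: Path | None = None          # GenBank directory (or use `simulate`)
    simulate: SimulationConfig | None = None
    tree: Path | None = None
    outgroup: str | None = None
    rates: Path | None = None
    mldist: Path | None = None  # independent per-taxon outgroup distances
    gene_classes: tuple[str, ...] = ("PCG", "rRNA", "tRNA")
    group_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    run_patterns: bool = True
    run_ancestral: bool = True
    run_composition: bool = True
    run_hermes: bool = True
    run_pca: bool = True
    run_correlations: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            targets = CompositionTargets(**sim.pop("targets", {}))
            clade = tuple(CompositionTargets(**t) for t in sim.pop("clade_targets", []))
            sim = SimulationConfig(targets=targets, clade_targets=clade, **sim)
        toggles = raw.pop("analyses", {})
        cfg = cls(
            out_dir=Path(raw.pop("out_dir", "mitoarch_out")),
            input_dir=Path(raw["input_dir"]) if raw.get("input_dir") else None,
            simulate=sim,
            tree=Path(raw["tree"]) if raw.get("tree") else None,
            outgroup=raw.pop("outgroup", None),
            rates=Path(raw["rates"]) if raw.get("rates") else None,
            mldist=Path(raw["mldist"]) if raw.get("mldist") else None,
            gene_classes=tuple(raw.pop("gene_classes", ("PCG", "rRNA", "tRNA"))),
            group_map=dict(raw.pop("group_map", {})),
            seed=int(raw.pop("seed", 0)),
            **{f"run_{k}": bool(v) for k, v in toggles.items()},
        )
        return cfg

    def validate(self) -> None:
        if self.input_dir is None and self.simulate is None:
            raise ValueError("config needs either input_dir or a simulate block")
        if self.run_hermes and self.tree is None and self.simulate is None:
            raise ValueError("the index stage requires a tree")
        if self.run_hermes and self.outgroup is None and self.simulate is None:
            raise ValueError("the index stage requires an outgroup id")
        if self.run_ancestral and self.tree is None and self.simulate is None:
            raise ValueError("ancestral reconstruction requires a tree")


def project_reference(reference: GeneOrder, gene_set: frozenset[str]) -> GeneOrder:
    """Restrict the reference arrangement to the dataset's shared gene set."""
    toks = [t for t in reference.tokens if t[0] in gene_set]
    if len(toks) < 3:
        raise ValueError("reference shares fewer than 3 genes with the dataset")
    return GeneOrder(reference.taxon_id, canonicalize(toks))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig) -> dict[str, Any]:
    """Execute all enabled stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": __version__, "seed": config.seed,
                                "stages": [], "inputs": {}}

    # ---- stage: acquire inputs -------------------------------------------
    if config.simulate is not None:
        sim = simulate_dataset(config.simulate, out_dir=out / "sim")
        input_dir = out / "sim" / "genbank"
        tree_path = out / "sim" / "tree.nwk"
        rates_path = out / "sim" / "rates.tsv"
        mldist_path = out / "sim" / "mldist.tsv"
        outgroup = config.simulate.outgroup_label
        manifest["stages"].append("simulate")
    else:
        input_dir = Path(config.input_dir)
        tree_path = config.tree
        rates_path = config.rates
        mldist_path = config.mldist
        outgroup = config.outgroup

    records = read_genbank_dir(input_dir)
    if not records:
        raise ValueError(f"no GenBank files found under {input_dir}")
    manifest["inputs"]["n_records"] = len(records)
    if tree_path is not None:
        manifest["inputs"]["tree_sha256"] = _sha256(Path(tree_path))

    ingroup = [r for r in records if r.taxon_id != outgroup]

    # ---- stage: gene orders ----------------------------------------------
    raw_orders = [extract_gene_order(r, config.gene_classes) for r in ingroup]
    orders, restriction_report = restrict_to_shared_genes(raw_orders)
    write_gene_orders_tsv(orders, out / "gene_orders.tsv", config.group_map)
    (out / "restriction_report.txt").write_text(
        "\n".join(restriction_report) + ("\n" if restriction_report else "")
    )
    manifest["stages"].append("orders")

    reference = project_reference(load_ground_pattern(), orders[0].gene_set)

    patterns = None
    if config.run_patterns:
        patterns = cluster_patterns(orders, config.group_map)
        write_patterns_tsv(patterns, out / "patterns.tsv")
        pcg_orders, _ = restrict_to_shared_genes(
            [extract_gene_order(r, ("PCG",)) for r in ingroup]
        )
        pcg_patterns = cluster_patterns(
            pcg_orders, config.group_map,
            ground_pattern=project_reference(load_ground_pattern(),
                                             pcg_orders[0].gene_set),
        )
        write_patterns_tsv(pcg_patterns, out / "patterns_pcg.tsv")
        amiga_values = amiga(pcg_patterns, len(pcg_orders))
        pd.DataFrame(sorted(amiga_values.items()),
                     columns=["taxon_id", "amiga"]).to_csv(
            out / "amiga.tsv", sep="\t", index=False)
        manifest["stages"].append("patterns")

    if config.run_ancestral and tree_path is not None:
        leaf_orders = {o.taxon_id: o for o in orders}
        import dendropy

        tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
        pruned = [lf.taxon for lf in tree.leaf_node_iter()
                  if lf.taxon.label not in leaf_orders]
        if pruned:
            tree.prune_taxa(pruned)
        rt = reconstruct(tree, leaf_orders, reference)
        edge_event_summary(rt, config.group_map).to_csv(
            out / "edge_events.tsv", sep="\t", index=False)
        for node in rt.tree.preorder_node_iter():
            if not node.is_leaf():
                node.label = rt.label_of(node)
        (out / "ancestral_tree.nwk").write_text(
            rt.tree.as_string(schema="newick", suppress_rooting=True))
        write_json(
            {"edges": [s.to_dict() for s in rt.edge_scenarios.values()]},
            out / "edge_scenarios.json",
        )
        manifest["stages"].append("ancestral")

    profiles_df = None
    if config.run_composition:
        profiles = [composition_profile(r) for r in ingroup]
        profiles_df = profiles_table(profiles)
        profiles_df.to_csv(out / "profiles.tsv", sep="\t", index=False)
        codon_long_table(profiles).to_csv(out / "codon_rscu.tsv", sep="\t", index=False)
        manifest["stages"].append("composition")

    hermes_result = None
    if config.run_hermes and tree_path is not None and profiles_df is not None:
        dist = tree_distances(str(tree_path), outgroup)
        if mldist_path is not None:
            # replace the tree-path outgroup distance (exactly collinear with
            # the root-to-tip distance when the outgroup roots the tree) by
            # the independently estimated pairwise distances
            ml = pd.read_csv(mldist_path, sep="\t").set_index("taxon_id")["ml_dist"]
            dist["ml_dist"] = dist["taxon_id"].map(ml)
        pcg_orders, _ = restrict_to_shared_genes(
            [extract_gene_order(r, ("PCG",)) for r in ingroup]
        )
        pcg_patterns = cluster_patterns(pcg_orders, config.group_map)
        amiga_values = amiga(pcg_patterns, len(pcg_orders))
        variables = build_variables(dist, profiles_df, amiga_values)
        hermes_result = fit_hermes(variables)
        write_json(hermes_result.to_dict(), out / "hermes.json")
        pd.DataFrame(sorted(hermes_result.scores.items()),
                     columns=["taxon_id", "hermes"]).to_csv(
            out / "hermes_scores.tsv", sep="\t", index=False)
        manifest["stages"].append("hermes")

    if config.run_pca and profiles_df is not None:
        table = profiles_df.drop(columns=["taxon_id"]).dropna(axis=1)
        pca = pca_correlation(table)
        pd.DataFrame(pca.loadings, index=pca.feature_names).to_csv(
            out / "pca_loadings.tsv", sep="\t")
        pd.DataFrame({"component": range(1, len(pca.variance_fractions) + 1),
                      "variance_fraction": pca.variance_fractions}).to_csv(
            out / "pca_variance.tsv", sep="\t", index=False)
        manifest["stages"].append("pca")

    if config.run_correlations and rates_path is not None:
        rates = pd.read_csv(rates_path, sep="\t")
        habitat = {t: g for t, g in config.group_map.items()} or None
        report = mgo_rate_correlation(orders, reference, rates, habitat,
                                      seed=config.seed)
        report.to_csv(out / "correlations.tsv", sep="\t", index=False)
        manifest["stages"].append("correlations")

    write_json(manifest, out / "manifest.json")
    return manifest
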