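"""Ancestral gene-order reconstruction on a rooted tree.

A candidate-parsimony scheme: ancestral states are restricted to the pool of
observed leaf orders plus the ancestral reference arrangement, and the
assignment minimising the total rearrangement-scenario length over all edges
(breakpoint distance as tie-breaker, then a preference for the reference so
derived states are not inflated) is found exactly with Sankoff-style dynamic
programming — a bottom-up cost table per candidate followed by a top-down
traceback.

Each internal node carries a consistency label mirroring the usual
three-level uncertainty convention: ``consistent`` (a unique optimum, stable
across both passes), ``intermediate`` (the passes disagreed, or a tie was
resolved by the reference preference) and ``fallback`` (an arbitrary,
deterministic tie-break). Every edge carries the inferred scenario from
parent to child order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import pandas as pd

from .gene_orders import GeneOrder, breakpoint_distance
from .rearrangement import Scenario, infer_scenario

logger = logging.getLogger(__name__)

LABELS = ("consistent", "intermediate", "fallback")


@dataclass
class ReconstructedTree:
    tree: dendropy.Tree
    node_orders: dict[int, GeneOrder]          # keyed by id(node)
    node_labels: dict[int, str]
    edge_scenarios: dict[tuple[int, int], Scenario]  # (id(parent), id(child))

    def order_of(self, node) -> GeneOrder:
        return self.node_orders[id(node)]

    def label_of(self, node) -> str:
        return self.node_labels[id(node)]


class _ScenarioCache:
    """Memoised scenario lengths between canonical orders."""

    def __init__(self):
        self._cache: dict[tuple, Scenario] = {}

    def scenario(self, a: GeneOrder, b: GeneOrder) -> Scenario:
        key = (a.tokens, b.tokens)
        if key not in self._cache:
            self._cache[key] = infer_scenario(a, b)
        return self._cache[key]

    def cost(self, a: GeneOrder, b: GeneOrder) -> tuple[int, int]:
        """(scenario length, breakpoint distance); surrogate length if incomplete."""
        if a.tokens == b.tokens:
            return 0, 0
        scen = self.scenario(a, b)
        bp = scen.breakpoints if scen.breakpoints is not None else breakpoint_distance(a, b)
        length = len(scen.events) if scen.complete else bp
        return length, bp


def _resolve_tree(tree: dendropy.Tree) -> dendropy.Tree:
    for node in tree.preorder_node_iter():
        if len(node.child_nodes()) > 2:
            logger.warning("resolving polytomy at %s with zero-length edges",
                           node.taxon.label if node.taxon else "<internal>")
    tree.resolve_polytomies(limit=2, update_bipartitions=False)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def _best_candidate(cands: list[GeneOrder], neighbours: list[GeneOrder],
                    reference: GeneOrder, cache: _ScenarioCache
                    ) -> tuple[GeneOrder, bool, bool]:
    """(winner, unique_optimum, tie_broken_arbitrarily) under summed cost."""
    seen: dict[tuple, GeneOrder] = {}
    for c in cands:
        seen.setdefault(c.tokens, c)
    scored = []
    for toks, cand in seen.items():
        ev = sum(cache.cost(cand, nb)[0] for nb in neighbours)
        bp = sum(cache.cost(cand, nb)[1] for nb in neighbours)
        scored.append((ev, bp, cand))
    best_ev, best_bp = min((ev, bp) for ev, bp, _ in scored)
    winners = [c for ev, bp, c in scored if (ev, bp) == (best_ev, best_bp)]
    if len(winners) == 1:
        return winners[0], True, False
    ref_winners = [c for c in winners if c.tokens == reference.tokens]
    if ref_winners:
        return ref_winners[0], False, False
    winners.sort(key=lambda c: c.tokens)
    return winners[0], False, True


def reconstruct(tree: dendropy.Tree | str, leaf_orders: Mapping[str, GeneOrder],
                reference: GeneOrder) -> ReconstructedTree:
    """Assign a gene order to every node and a scenario to every edge.

    Every leaf label must map to a canonical, gene-restricted order over a
    common gene set (the reference included).
    """
    if not isinstance(tree, dendropy.Tree):
        data = str(tree)
        tree = (dendropy.Tree.get(data=data, schema="newick")
                if data.strip().startswith("(")
                else dendropy.Tree.get(path=data, schema="newick"))
    tree = _resolve_tree(tree)

    gene_set = reference.gene_set
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in leaf_orders:
            raise ValueError(f"leaf {label!r} has no gene order")
        if leaf_orders[label].gene_set != gene_set:
            raise ValueError(
                f"leaf {label!r} gene set differs from the reference; "
                "apply restrict_to_shared_genes"
            )

    cache = _ScenarioCache()
    orders: dict[int, GeneOrder] = {}
    labels: dict[int, str] = {}

    # ---- candidate pool: every distinct leaf order plus the reference.
    # Ancestral states are restricted to this pool; the assignment is then
    # solved exactly by Sankoff-style dynamic programming, so the total
    # event count is globally minimal over the pool.
    pool: dict[tuple, GeneOrder] = {reference.tokens: reference}
    for o in leaf_orders.values():
        pool.setdefault(o.tokens, o)
    cands = list(pool.values())
    idx_of = {c.tokens: i for i, c in enumerate(cands)}
    ref_idx = idx_of[reference.tokens]
    INF = float("inf")

    def dist(i: int, j: int) -> tuple[int, int]:
        return cache.cost(cands[i], cands[j])

    # bottom-up DP: cost[v][i] = minimal (events, breakpoints) in v's subtree
    # when v is assigned candidate i (lexicographic on the pair)
    cost: dict[int, list[tuple[float, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            li = idx_of[leaf_orders[node.taxon.label].tokens]
            cost[id(node)] = [
                (0.0, 0.0) if i == li else (INF, INF) for i in range(len(cands))
            ]
            continue
        rows = []
        for i in range(len(cands)):
            ev_tot, bp_tot = 0.0, 0.0
            for ch in node.child_nodes():
                child_cost = cost[id(ch)]
                best = (INF, INF)
                for j in range(len(cands)):
                    if child_cost[j][0] == INF:
                        continue
                    d_ev, d_bp = dist(i, j)
                    cand = (child_cost[j][0] + d_ev, child_cost[j][1] + d_bp)
                    if cand < best:
                        best = cand
                ev_tot += best[0]
                bp_tot += best[1]
            rows.append((ev_tot, bp_tot))
        cost[id(node)] = rows

    def _pick(indices: list[int], prefer: int | None) -> int:
        """Tie-break: ancestral reference first, then the parent's state,
        then the lexicographically smallest candidate."""
        if ref_idx in indices:
            return ref_idx
        if prefer is not None and prefer in indices:
            return prefer
        return min(indices, key=lambda i: cands[i].tokens)

    # top-down traceback
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            orders[id(node)] = leaf_orders[node.taxon.label]
            continue
        rows = cost[id(node)]
        if node.parent_node is None:
            best = min(rows)
            winners = [i for i, r in enumerate(rows) if r == best]
            orders[id(node)] = cands[_pick(winners, None)]
        else:
            pi = idx_of[orders[id(node.parent_node)].tokens]
            scored = []
            for i, r in enumerate(rows):
                if r[0] == INF:
                    continue
                d_ev, d_bp = dist(pi, i)
                scored.append(((r[0] + d_ev, r[1] + d_bp), i))
            best = min(s for s, _ in scored)
            winners = [i for s, i in scored if s == best]
            orders[id(node)] = cands[_pick(winners, pi)]

    # ---- label pass: local optimality of the final assignment
    # consistent: the assignment is the unique local optimum, or a tie the
    # reference preference resolves in its favour; intermediate: the local
    # re-evaluation prefers a different candidate (the passes conflict);
    # fallback: an arbitrary tie-break.
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        assigned = orders[id(node)]
        neighbours = [orders[id(ch)] for ch in node.child_nodes()]
        if node.parent_node is not None:
            neighbours.append(orders[id(node.parent_node)])
        cands = neighbours + [reference, assigned]
        winner, unique, arbitrary = _best_candidate(cands, neighbours, reference, cache)
        if arbitrary:
            labels[id(node)] = "fallback"
        elif winner.tokens == assigned.tokens:
            labels[id(node)] = "consistent"
        else:
            labels[id(node)] = "intermediate"

    scenarios: dict[tuple[int, int], Scenario] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            scenarios[(id(node), id(child))] = cache.scenario(
                orders[id(node)], orders[id(child)]
            )
    return ReconstructedTree(tree=tree, node_orders=orders,
                             node_labels=labels, edge_scenarios=scenarios)


def edge_event_summary(rt: ReconstructedTree,
                       group_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-edge event table: parent, child, n_events, per-type counts, flags."""
    group_map = group_map or {}

    def _name(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return f"node{id(node) % 100000}"

    names: dict[int, str] = {}
    counter = 0
    for node in rt.tree.preorder_node_iter():
        if node.taxon is not None:
            names[id(node)] = node.taxon.label
        else:
            names[id(node)] = f"N{counter}"
            counter += 1

    rows = []
    for (pid, cid), scen in rt.edge_scenarios.items():
        counts = {t: 0 for t in ("T", "r", "rT", "tdrl", "d", "x")}
        for ev in scen.events:
            counts[ev.type] += 1
        child_name = names[cid]
        rows.append({
            "parent": names[pid],
            "child": child_name,
            "group": group_map.get(child_name, ""),
            "n_events": len(scen.events),
            **{f"n_{t}": c for t, c in counts.items()},
            "complete": scen.complete,
        })
    return pd.DataFrame(rows)
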