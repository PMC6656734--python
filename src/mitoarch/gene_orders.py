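"""Circular signed gene orders (MGOs): canonical form, clustering, distances.

A mitochondrial gene order (MGO) is a circular arrangement of signed gene
tokens; the sign records the coding strand. Because a circular molecule has
no intrinsic start or strand, two deposited records that differ only by
rotation or by which strand was submitted describe the same MGO. The
canonical form fixes both: rotate so the anchor gene (cox1 by default) comes
first and, if the anchor reads on the minority strand, reflect the whole
order (reverse the list and flip every sign) before re-rotating.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

from . import vocab

logger = logging.getLogger(__name__)

SignedToken = tuple[str, int]

#: anchor preference: cox1, then fallbacks (all decapod mitogenomes carry cox1)
ANCHOR_PRIORITY = ("cox1", "cob", "rrnL")


# ---------------------------------------------------------------------------
# signed-token parsing / formatting ("-trnC" style)
# ---------------------------------------------------------------------------

def parse_signed_token(text: str) -> SignedToken:
    text = text.strip()
    if text.startswith("-"):
        return text[1:], -1
    if text.startswith("+"):
        return text[1:], +1
    return text, +1


def format_signed_token(tok: SignedToken) -> str:
    name, sign = tok
    return f"-{name}" if sign < 0 else name


def parse_order_string(text: str) -> tuple[SignedToken, ...]:
    return tuple(parse_signed_token(t) for t in text.split())


def format_order_string(tokens: Sequence[SignedToken]) -> str:
    return " ".join(format_signed_token(t) for t in tokens)


# ---------------------------------------------------------------------------
# canonicalisation
# ---------------------------------------------------------------------------

def _reflect(tokens: Sequence[SignedToken]) -> tuple[SignedToken, ...]:
    """Read the circle from the other strand: reverse order, flip signs."""
    return tuple((name, -sign) for name, sign in reversed(tokens))


def _rotations_to(tokens: Sequence[SignedToken], anchor: str) -> list[tuple[SignedToken, ...]]:
    n = len(tokens)
    out = []
    for i, (name, sign) in enumerate(tokens):
        if name == anchor and sign > 0:
            out.append(tuple(tokens[i:]) + tuple(tokens[:i]))
    return out


def pick_anchor(names: Iterable[str], priority: Sequence[str] = ANCHOR_PRIORITY) -> str:
    present = set(names)
    for cand in priority:
        if cand in present:
            return cand
    return min(present)


def canonicalize(tokens: Sequence[SignedToken],
                 anchor_priority: Sequence[str] = ANCHOR_PRIORITY) -> tuple[SignedToken, ...]:
    """Canonical representative of the circular signed order.

    Among all rotations of the order and of its reflection that start with a
    plus-strand copy of the anchor gene, the lexicographically smallest is
    returned. With a unique anchor copy this reduces to the simple rule
    "rotate to the anchor; reflect first if the anchor reads minus".
    Idempotent and invariant under rotation and reflection.
    """
    if not tokens:
        raise ValueError("cannot canonicalise an empty gene order")
    anchor = pick_anchor(name for name, _ in tokens)
    candidates = _rotations_to(tokens, anchor) + _rotations_to(_reflect(tokens), anchor)
    if not candidates:
        raise ValueError(f"anchor gene {anchor!r} unusable in order {tokens!r}")
    return min(candidates)


@dataclass(frozen=True)
class GeneOrder:
    """Canonical circular signed gene order for one taxon."""

    taxon_id: str
    tokens: tuple[SignedToken, ...]

    @classmethod
    def from_tokens(cls, taxon_id: str, tokens: Iterable[SignedToken]) -> "GeneOrder":
        return cls(taxon_id=taxon_id, tokens=canonicalize(tuple(tokens)))

    @property
    def gene_multiset(self) -> Counter:
        return Counter(name for name, _ in self.tokens)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(name for name, _ in self.tokens)

    def same_arrangement(self, other: "GeneOrder") -> bool:
        return self.tokens == other.tokens

    def __len__(self) -> int:
        return len(self.tokens)


def load_ground_pattern() -> GeneOrder:
    """The pancrustacean ground pattern (Gr), shipped as editable data."""
    text = resources.files("mitoarch.data").joinpath("ground_pattern.txt").read_text()
    toks = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks.append(parse_signed_token(line))
    return GeneOrder.from_tokens("Gr", toks)


# ---------------------------------------------------------------------------
# extraction from annotation records
# ---------------------------------------------------------------------------

def extract_gene_order(record, gene_classes: Iterable[str] = ("PCG", "rRNA", "tRNA")) -> GeneOrder:
    """Build the canonical gene order of a :class:`MitogenomeRecord`.

    Features of the requested classes are sorted by start coordinate (an
    origin-spanning feature sorts by its start) and mapped to signed tokens.
    """
    classes = set(gene_classes)
    feats = [f for f in record.features if f.kind in classes]
    if not feats:
        raise ValueError(f"{record.taxon_id}: no features of classes {sorted(classes)}")
    feats.sort(key=lambda f: (f.start, f.end))
    tokens = [(f.token, f.strand) for f in feats]
    return GeneOrder.from_tokens(record.taxon_id, tokens)


# ---------------------------------------------------------------------------
# shared-gene restriction
# ---------------------------------------------------------------------------

def restrict_to_shared_genes(orders: Sequence[GeneOrder]) -> tuple[list[GeneOrder], list[str]]:
    """Drop genes missing from any taxon and collapse duplicate copies.

    Genes absent from at least one taxon are deleted from all orders; within
    a taxon only the first copy (in canonical reading order) of a duplicated
    gene is retained. Returns the re-canonicalised orders and a report of
    every deletion.
    """
    if len(orders) < 2:
        raise ValueError("need at least two orders to restrict")
    shared = frozenset.intersection(*(o.gene_set for o in orders))
    if len(shared) < 3:
        raise ValueError(
            f"shared gene set has only {len(shared)} genes; orders are incomparable"
        )
    report: list[str] = []
    out: list[GeneOrder] = []
    for order in orders:
        seen: set[str] = set()
        kept: list[SignedToken] = []
        for name, sign in order.tokens:
            if name not in shared:
                report.append(f"{order.taxon_id}: dropped unshared gene {name}")
                continue
            if name in seen:
                report.append(f"{order.taxon_id}: collapsed duplicate copy of {name}")
                continue
            seen.add(name)
            kept.append((name, sign))
        out.append(GeneOrder.from_tokens(order.taxon_id, kept))
    for line in report:
        logger.warning("restrict_to_shared_genes: %s", line)
    return out, report


# ---------------------------------------------------------------------------
# pattern clustering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MGOPattern:
    """A cluster of taxa sharing an identical canonical gene order."""

    pattern_id: str
    exemplar: GeneOrder
    members: tuple[str, ...]

    @property
    def count(self) -> int:
        return len(self.members)


def cluster_patterns(orders: Sequence[GeneOrder],
                     prefix_map: Mapping[str, str] | None = None,
                     ground_pattern: GeneOrder | None = None) -> list[MGOPattern]:
    """Partition orders by exact arrangement equality into MGO patterns.

    The pattern matching the ground pattern is labelled "Gr"; every other
    pattern gets its group prefix (from ``prefix_map``, default "Mt") plus a
    sequential index in order of first appearance. Deterministic given the
    input order.
    """
    prefix_map = prefix_map or {}
    if ground_pattern is None:
        ground_pattern = load_ground_pattern()
    gr_tokens = ground_pattern.tokens
    # restriction may have removed genes from the dataset: project Gr as well
    if orders:
        dataset_genes = orders[0].gene_set
        projected = [t for t in gr_tokens if t[0] in dataset_genes]
        if len(projected) >= 3 and len(projected) < len(gr_tokens):
            gr_tokens = canonicalize(projected)

    groups: dict[tuple[SignedToken, ...], list[str]] = {}
    first_seen: list[tuple[SignedToken, ...]] = []
    exemplars: dict[tuple[SignedToken, ...], GeneOrder] = {}
    for order in orders:
        if order.tokens not in groups:
            groups[order.tokens] = []
            first_seen.append(order.tokens)
            exemplars[order.tokens] = order
        groups[order.tokens].append(order.taxon_id)

    counters: Counter = Counter()
    patterns: list[MGOPattern] = []
    for toks in first_seen:
        members = tuple(groups[toks])
        if toks == gr_tokens:
            pid = "Gr"
        else:
            prefix = prefix_map.get(members[0], "Mt")
            counters[prefix] += 1
            pid = f"{prefix}{counters[prefix]}"
        patterns.append(MGOPattern(pattern_id=pid, exemplar=exemplars[toks], members=members))
    return patterns


def amiga(patterns: Sequence[MGOPattern], n_taxa: int) -> dict[str, float]:
    """Fraction of the dataset sharing each taxon's (PCG) arrangement.

    AMIGA(taxon) = size of the taxon's pattern / number of taxa; in (0, 1].
    """
    values: dict[str, float] = {}
    for pat in patterns:
        for taxon in pat.members:
            values[taxon] = pat.count / n_taxa
    return values


# ---------------------------------------------------------------------------
# breakpoint distance
# ---------------------------------------------------------------------------

def _adjacency_set(tokens: Sequence[SignedToken]) -> frozenset:
    """Signed circular adjacencies with (x, y) identified with (-y, -x)."""
    n = len(tokens)
    adjs = set()
    for i in range(n):
        x = tokens[i]
        y = tokens[(i + 1) % n]
        a = (x, y)
        b = ((y[0], -y[1]), (x[0], -x[1]))
        adjs.add(min(a, b))
    return frozenset(adjs)


def breakpoint_distance(o1: GeneOrder, o2: GeneOrder) -> int:
    """Number of signed circular adjacencies of ``o1`` absent from ``o2``."""
    if o1.gene_multiset != o2.gene_multiset:
        raise ValueError(
            "breakpoint_distance requires identical gene sets; "
            "apply restrict_to_shared_genes first"
        )
    return len(_adjacency_set(o1.tokens) - _adjacency_set(o2.tokens))
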