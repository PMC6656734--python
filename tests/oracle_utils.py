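"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles — naive list surgery and
exhaustive enumeration — deliberately sharing no code with the package's
inference machinery, so the two routes cross-check each other.
"""

from __future__ import annotations

import itertools
from collections import deque

Tok = tuple[str, int]


# ---------------------------------------------------------------------------
# naive circular canonicaliser (anchor = alphabetically smallest token name,
# overridden by cox1 when present, matching the package's convention)
# ---------------------------------------------------------------------------

def naive_canonical(tokens: list[Tok], anchor_priority=("cox1", "cob", "rrnL")) -> tuple[Tok, ...]:
    names = {t[0] for t in tokens}
    anchor = next((a for a in anchor_priority if a in names), min(names))
    variants = []
    reflected = [(g, -s) for g, s in reversed(tokens)]
    for seq in (tokens, reflected):
        for i in range(len(seq)):
            rot = seq[i:] + seq[:i]
            if rot[0][0] == anchor and rot[0][1] > 0:
                variants.append(tuple(rot))
    return min(variants)


# ---------------------------------------------------------------------------
# naive single-event products (r, T, rT) as canonical forms
# ---------------------------------------------------------------------------

def all_reversals(tokens: list[Tok]):
    n = len(tokens)
    for i in range(n):
        for j in range(i + 1, n + 1):
            seg = [(g, -s) for g, s in reversed(tokens[i:j])]
            yield "r", naive_canonical(tokens[:i] + seg + tokens[j:])


def all_transpositions(tokens: list[Tok], flip: bool = False):
    n = len(tokens)
    kind = "rT" if flip else "T"
    for i in range(n):
        for j in range(i + 1, n + 1):
            seg = tokens[i:j]
            if flip:
                seg = [(g, -s) for g, s in reversed(seg)]
            rest = tokens[:i] + tokens[j:]
            for k in range(len(rest) + 1):
                yield kind, naive_canonical(rest[:k] + seg + rest[k:])


def single_event_types(source: list[Tok], target_canonical: tuple[Tok, ...]) -> set[str]:
    """Which of r/T/rT can turn source into target in one step."""
    types = set()
    for kind, prod in all_reversals(source):
        if prod == target_canonical:
            types.add(kind)
            break
    for flip in (False, True):
        for kind, prod in all_transpositions(source, flip):
            if prod == target_canonical:
                types.add(kind)
                break
    return types


# ---------------------------------------------------------------------------
# BFS oracle for the tdrl distance on linear permutations
# ---------------------------------------------------------------------------

def tdrl_successors(perm: tuple[int, ...]):
    """All products of one whole-sequence tdrl (subwindow tdrls are subsumed)."""
    n = len(perm)
    for bits in range(1, 2 ** n - 1):
        first = [perm[p] for p in range(n) if (bits >> p) & 1]
        second = [perm[p] for p in range(n) if not (bits >> p) & 1]
        yield tuple(first + second)


def bfs_tdrl_distances(n: int) -> dict[tuple[int, ...], int]:
    """tdrl distance from the identity to every permutation of 1..n."""
    start = tuple(range(1, n + 1))
    dist = {start: 0}
    queue = deque([start])
    while queue:
        cur = queue.popleft()
        for nxt in tdrl_successors(cur):
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                queue.append(nxt)
    return dist
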