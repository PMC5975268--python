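"""TDRL distances between linear and circular gene orders.

With unit cost per event it suffices to consider whole-genome TDRLs, and
the linear distance has a closed form: relabel the source by positions in
the target, count the maximal value-consecutive increasing runs ``k`` of
that permutation, and the distance is ``ceil(log2 k)``.  For circular
orders the distance is minimized over all pairs of linearizations — an
unfavorable choice of representatives can overestimate it.  A
breadth-first-search oracle over all triples provides ground truth for
small gene counts.
"""

from __future__ import annotations

from typing import Sequence

from .errors import GeneSetMismatchError
from .orders import CircularGeneOrder, relabel_by_target

BFS_MAX_N = 8

#: neighbor cache for the BFS oracle, keyed by canonical state tuple
_NEIGHBORS: dict = {}


def increasing_substring_count(w: Sequence[int]) -> int:
    """Number of maximal value-consecutive increasing runs of ``w``.

    Values ``v`` and ``v+1`` share a run iff ``v`` appears before ``v+1``
    in ``w``.  ``k == 1`` iff ``w`` is the identity; a strictly decreasing
    ``w`` has ``k == n``.
    """
    n = len(w)
    if sorted(w) != list(range(1, n + 1)):
        raise ValueError(f"not a permutation of [1:{n}]: {list(w)}")
    pos = {v: i for i, v in enumerate(w)}
    return 1 + sum(1 for v in range(1, n) if pos[v + 1] < pos[v])


def linear_tdrl_distance(
    source_rep: Sequence, target_rep: Sequence
) -> int:
    """Minimum number of TDRLs transforming one linear order into another.

    ``ceil(log2 k)`` where ``k`` is the increasing-substring count of the
    source relabelled by target positions.  Not symmetric in general.
    """
    w = relabel_by_target(source_rep, target_rep)
    k = increasing_substring_count(w)
    return (k - 1).bit_length()


def circular_tdrl_distance(
    a: CircularGeneOrder, b: CircularGeneOrder
) -> int:
    """Directed TDRL distance between circular orders.

    Minimum of the linear distance over all ``n x n`` pairs of
    linearizations of ``a`` and ``b``; zero iff the classes are equal.
    """
    if a.genes != b.genes:
        raise GeneSetMismatchError(
            f"gene sets differ: {sorted(map(str, a.genes ^ b.genes))}"
        )
    if a == b:
        return 0
    best = None
    for ra in a.representatives():
        for rb in b.representatives():
            d = linear_tdrl_distance(ra, rb)
            if best is None or d < best:
                best = d
                if best == 1:  # cannot go lower for distinct classes
                    return 1
    return best


def distance_both_directions(
    a: CircularGeneOrder, b: CircularGeneOrder
) -> tuple:
    """``(d(a, b), d(b, a))``."""
    return circular_tdrl_distance(a, b), circular_tdrl_distance(b, a)


def _neighbors(state: tuple) -> frozenset:
    """Canonical tuples reachable from ``state`` by one TDRL (brute force).

    Tries every triple: all origins and all ``2^n`` bipartitions.
    """
    cached = _NEIGHBORS.get(state)
    if cached is not None:
        return cached
    n = len(state)
    smallest = min(state)
    out = set()
    for oi in range(n):
        rep = state[oi:] + state[:oi]
        for mask in range(1 << n):
            first = [rep[i] for i in range(n) if mask >> i & 1]
            second = [rep[i] for i in range(n) if not mask >> i & 1]
            seq = tuple(first + second)
            start = seq.index(smallest)
            out.add(seq[start:] + seq[:start])
    result = frozenset(out)
    _NEIGHBORS[state] = result
    return result


def bfs_distance_oracle(
    a: CircularGeneOrder, b: CircularGeneOrder, max_depth: int = 6
) -> int:
    """Exact TDRL distance by breadth-first search over all triples.

    Ground truth for small ``n`` (guard: ``n <= 8``); raises if the
    distance exceeds ``max_depth``.
    """
    if a.genes != b.genes:
        raise GeneSetMismatchError(
            f"gene sets differ: {sorted(map(str, a.genes ^ b.genes))}"
        )
    if a.n > BFS_MAX_N:
        raise ValueError(
            f"n = {a.n} exceeds the BFS guard ({BFS_MAX_N}); "
            "use circular_tdrl_distance instead"
        )
    if max_depth < 0:
        raise ValueError("max_depth must be non-negative")
    start, goal = a.canonical, b.canonical
    if start == goal:
        return 0
    frontier = {start}
    seen = {start}
    for depth in range(1, max_depth + 1):
        nxt = set()
        for s in frontier:
            for t in _neighbors(s):
                if t == goal:
                    return depth
                if t not in seen:
                    seen.add(t)
                    nxt.add(t)
        frontier = nxt
        if not frontier:
            break
    raise ValueError(f"distance exceeds max_depth = {max_depth}")
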