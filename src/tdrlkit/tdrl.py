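"""TDRL triples, their action on circular orders, and partial duplications.

A tandem duplication random loss (TDRL) event tandem-duplicates the whole
genome starting at an origin gene ``p`` and then loses exactly one copy of
every gene.  It is written as a triple ``(F, S, p)`` where ``(F, S)`` is a
bipartition of the gene set: genes of ``F`` keep their first copy, genes
of ``S`` keep their second copy.  Reading the kept occurrences of the
duplicated intermediate yields the rearranged order: the genes of ``F``
move in front of the genes of ``S`` with relative order preserved within
each set.  Interchanging ``F`` and ``S`` leaves the resulting circular
order unchanged.

Every TDRL is also realizable as a *partial* duplication that copies only
a contiguous window ``W`` of the origin representative; the minimal such
window runs from the first ``S``-gene to the last ``F``-gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

from .errors import GeneSetMismatchError
from .orders import CircularGeneOrder

Label = Hashable


@dataclass(frozen=True)
class Tdrl:
    """A whole-genome TDRL triple ``(F, S, p)``.

    ``first`` (F) and ``second`` (S) are the genes kept in the first and
    second copy of the duplicated intermediate; ``origin`` (p) is the gene
    at which the duplication conceptually starts.  Empty ``first`` or
    ``second`` is allowed and denotes an identity map.
    """

    first: frozenset
    second: frozenset
    origin: Label

    def __post_init__(self):
        object.__setattr__(self, "first", frozenset(self.first))
        object.__setattr__(self, "second", frozenset(self.second))
        if self.first & self.second:
            raise ValueError(
                f"F and S overlap: {sorted(map(str, self.first & self.second))}"
            )
        if self.origin not in self.first | self.second:
            raise ValueError(f"origin {self.origin!r} not in the gene set")

    @property
    def genes(self) -> frozenset:
        return self.first | self.second

    def swap(self) -> "Tdrl":
        """The relabelled triple ``(S, F, p)``; same action on every order."""
        return Tdrl(self.second, self.first, self.origin)

    def __repr__(self):
        f = ",".join(map(str, sorted(self.first, key=str)))
        s = ",".join(map(str, sorted(self.second, key=str)))
        return f"Tdrl(({{{f}}},{{{s}}},{self.origin}))"


def swap_labeling(t: Tdrl) -> Tdrl:
    """Interchange the kept-first and kept-second sets (an involution)."""
    return t.swap()


def _check_gene_sets(t: Tdrl, order: CircularGeneOrder):
    if t.genes != order.genes:
        only_t = t.genes - order.genes
        only_o = order.genes - t.genes
        raise GeneSetMismatchError(
            f"TDRL gene set differs from order (only in TDRL: "
            f"{sorted(map(str, only_t))}, only in order: {sorted(map(str, only_o))})"
        )


def apply_tdrl(t: Tdrl, order: CircularGeneOrder) -> CircularGeneOrder:
    """The circular order produced by ``t`` acting on ``order``.

    Result: the class of (F-genes of the origin representative in order,
    then S-genes in order).  Depends only on the rotation class of the
    input, never on its stored representative.
    """
    _check_gene_sets(t, order)
    rep = order.representative_starting_at(t.origin)
    kept_first = [g for g in rep if g in t.first]
    kept_second = [g for g in rep if g in t.second]
    return CircularGeneOrder(kept_first + kept_second)


def is_identity_tdrl(t: Tdrl, order: CircularGeneOrder) -> bool:
    """True iff ``t`` maps ``order`` to itself."""
    return apply_tdrl(t, order) == order


@dataclass(frozen=True)
class Occurrence:
    """One of the ``2n`` gene copies in a duplicated intermediate."""

    gene: Label
    copy: int  # 1 or 2
    kept: bool


@dataclass(frozen=True)
class DuplicatedIntermediate:
    """The 2n-gene tandem-duplicated state before the losses.

    Occurrences 1..n are the origin representative (copy 1), occurrences
    n+1..2n repeat it (copy 2).  A copy-1 occurrence is kept iff its gene
    is in F; a copy-2 occurrence iff its gene is in S — so every gene is
    kept exactly once and lost exactly once.
    """

    occurrences: tuple
    origin: Label

    @property
    def kept_reading(self) -> tuple:
        """Kept occurrences in order; a representative of the output."""
        return tuple(o.gene for o in self.occurrences if o.kept)

    @property
    def lost(self) -> tuple:
        return tuple(o.gene for o in self.occurrences if not o.kept)


def build_duplicated_intermediate(
    t: Tdrl, order: CircularGeneOrder
) -> DuplicatedIntermediate:
    """Materialize the tandem-duplicated intermediate of ``t`` on ``order``."""
    _check_gene_sets(t, order)
    rep = order.representative_starting_at(t.origin)
    occ = [Occurrence(g, 1, g in t.first) for g in rep]
    occ += [Occurrence(g, 2, g in t.second) for g in rep]
    return DuplicatedIntermediate(tuple(occ), t.origin)


@dataclass(frozen=True)
class PartialTdrl:
    """A TDRL realized as a duplication of only a contiguous window ``W``.

    ``window`` is a contiguous subsequence of the origin representative
    (never wrapping past its end); ``kept_first``/``kept_second`` split the
    window genes by which copy survives; ``not_duplicated`` (N) are the
    untouched genes outside the window.
    """

    window: tuple
    kept_first: tuple
    kept_second: tuple
    not_duplicated: frozenset
    origin: Label

    @property
    def size(self) -> int:
        """Number of duplicated genes, |W|."""
        return len(self.window)


def minimal_partial(t: Tdrl, order: CircularGeneOrder) -> PartialTdrl:
    """The smallest-window partial duplication realizing ``t`` on ``order``.

    Within the origin representative the window runs from the first
    S-gene through the last F-gene; everything before it is untouched
    F-prefix, everything after it untouched S-suffix.  When the last
    F-gene precedes the first S-gene the triple is an identity map and
    the window is empty.  Note the window is specific to the labeling:
    ``t`` and ``t.swap()`` generally have different minimal windows.
    """
    _check_gene_sets(t, order)
    rep = order.representative_starting_at(t.origin)
    first_s = next((i for i, g in enumerate(rep) if g in t.second), None)
    last_f = next(
        (i for i in range(len(rep) - 1, -1, -1) if rep[i] in t.first), None
    )
    if first_s is None or last_f is None or last_f < first_s:
        return PartialTdrl((), (), (), frozenset(rep), t.origin)
    window = rep[first_s : last_f + 1]
    return PartialTdrl(
        window=window,
        kept_first=tuple(g for g in window if g in t.first),
        kept_second=tuple(g for g in window if g in t.second),
        not_duplicated=frozenset(rep[:first_s] + rep[last_f + 1 :]),
        origin=t.origin,
    )


def apply_partial(partial: PartialTdrl, order: CircularGeneOrder) -> CircularGeneOrder:
    """Replay a partial duplication: replace ``W`` by F'-then-S' in place."""
    rep = order.representative_starting_at(partial.origin)
    if not partial.window:
        return order
    w = len(partial.window)
    for start in range(len(rep) - w + 1):
        if rep[start : start + w] == partial.window:
            new = (
                rep[:start]
                + partial.kept_first
                + partial.kept_second
                + rep[start + w :]
            )
            return CircularGeneOrder(new)
    raise ValueError("window is not a contiguous run of the origin representative")


def whole_from_partial(partial: PartialTdrl, order: CircularGeneOrder) -> Tdrl:
    """The whole-genome TDRL with the same effect as a partial duplication.

    ``F = S'``, ``S = N ∪ F'`` and the origin is the gene immediately
    following the window along the circle (the unique non-duplicated gene
    adjacent to the second copy in the partially duplicated intermediate).
    """
    if not partial.window:
        raise ValueError("empty window: the partial duplication is an identity map")
    rep = order.representative_starting_at(partial.window[0])
    w = len(partial.window)
    if rep[:w] != partial.window:
        raise ValueError("window is not contiguous in the circular order")
    p = rep[w % len(rep)]
    return Tdrl(
        first=frozenset(partial.kept_second),
        second=partial.not_duplicated | frozenset(partial.kept_first),
        origin=p,
    )
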