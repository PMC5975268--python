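"""Circular gene orders as rotation-equivalence classes of permutations.

A unichromosomal circular genome without duplicate genes is modelled as a
circular permutation: the equivalence class of all rotations of a linear
gene sequence.  Equality, hashing and all downstream algebra are
rotation-invariant.  Gene labels may be arbitrary sortable hashables
(integers ``1..n`` in the formal setting, gene-name strings for real
mitochondrial data); a :class:`LabelMap` converts between the two views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Sequence

from .errors import GeneSetMismatchError, InputFormatError

logger = logging.getLogger(__name__)

Label = Hashable


def shift_k(representative: Sequence[Label], k: int) -> tuple:
    """Apply the rotation (shift) operation ``k`` times.

    One shift moves the first element to the back:
    ``(a b ... z) -> (b ... z a)``.  ``shift_k(r, n) == tuple(r)``.
    """
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    r = tuple(representative)
    if not r:
        return r
    k %= len(r)
    return r[k:] + r[:k]


@dataclass(frozen=True)
class LabelMap:
    """Bijection between gene labels and the integers ``1..n``.

    Lets named gene orders use the integer-permutation formalism: the
    integer of a gene is one plus its index in ``labels``.
    """

    labels: tuple

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be distinct")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_int(self, label: Label) -> int:
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown gene label {label!r}") from None

    def to_label(self, i: int) -> Label:
        if not 1 <= i <= self.n:
            raise KeyError(f"integer {i} outside [1:{self.n}]")
        return self.labels[i - 1]

    def ints_of(self, seq: Iterable[Label]) -> tuple:
        return tuple(self.to_int(x) for x in seq)

    def labels_of(self, seq: Iterable[int]) -> tuple:
        return tuple(self.to_label(i) for i in seq)


class GeneOrder:
    """A linear reading of a gene order: distinct labels, strands discarded."""

    __slots__ = ("names",)

    def __init__(self, names: Sequence[Label]):
        names = tuple(names)
        if not names:
            raise InputFormatError("empty gene order")
        seen = set()
        for g in names:
            if g in seen:
                raise InputFormatError(f"duplicate gene {g!r} in gene order")
            seen.add(g)
        self.names = names

    @property
    def n(self) -> int:
        return len(self.names)

    def circular(self) -> "CircularGeneOrder":
        return CircularGeneOrder(self.names)

    def __repr__(self):
        return f"GeneOrder({list(self.names)!r})"


def _canonical_rotation(seq: tuple) -> tuple:
    """Rotation starting at the smallest label (deterministic class anchor)."""
    start = seq.index(min(seq))
    return seq[start:] + seq[:start]


class CircularGeneOrder:
    """Rotation-equivalence class of a gene sequence.

    The stored representative is the rotation beginning with the smallest
    label, so tuple equality of ``canonical`` decides class equality and
    the class is hashable.
    """

    __slots__ = ("canonical", "_posmap")

    def __init__(self, representative: Sequence[Label]):
        seq = tuple(representative)
        if not seq:
            raise ValueError("a circular gene order needs at least one gene")
        if len(set(seq)) != len(seq):
            dup = next(g for g in seq if seq.count(g) > 1)
            raise ValueError(f"duplicate gene {dup!r} in circular order")
        canonical = _canonical_rotation(seq)
        object.__setattr__(self, "canonical", canonical)
        object.__setattr__(
            self, "_posmap", {g: i for i, g in enumerate(canonical)}
        )

    @property
    def n(self) -> int:
        return len(self.canonical)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.canonical)

    def __contains__(self, gene: Label) -> bool:
        return gene in self._posmap

    def representative_starting_at(self, p: Label) -> tuple:
        """The unique linearization of the class beginning with gene ``p``."""
        try:
            i = self._posmap[p]
        except KeyError:
            raise KeyError(f"gene {p!r} not in this order") from None
        return self.canonical[i:] + self.canonical[:i]

    def representatives(self) -> list:
        """All ``n`` linearizations, ordered along the canonical rotation."""
        return [self.representative_starting_at(p) for p in self.canonical]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CircularGeneOrder):
            return NotImplemented
        return self.canonical == other.canonical

    def __hash__(self):
        return hash(self.canonical)

    def __repr__(self):
        return f"CircularGeneOrder({list(self.canonical)!r})"


def circular_equals(a: CircularGeneOrder, b: CircularGeneOrder) -> bool:
    """True iff some rotation of one representative equals the other."""
    return a == b


def parse_gene_order_text(text: str, origin: str = "<string>") -> list:
    """Parse FASTA-like gene-order records from a string.

    Records start with a ``>`` header line; following non-empty lines hold
    whitespace-separated gene names, optionally prefixed with a strand sign
    (``+``/``-``), which is parsed and discarded: a tandem duplication
    random loss never changes gene strandedness.
    """
    records: list = []
    name = None
    genes: list = []
    signs_seen = False

    def close():
        nonlocal name, genes
        if name is None:
            return
        if not genes:
            raise InputFormatError(f"{origin}: empty record {name!r}")
        try:
            records.append((name, GeneOrder(genes)))
        except InputFormatError as e:
            raise InputFormatError(f"{origin}: record {name!r}: {e}") from None
        name, genes = None, []

    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            close()
            name = line[1:].strip() or f"record{len(records) + 1}"
            genes = []
        else:
            if name is None:
                raise InputFormatError(
                    f"{origin}: gene names before any '>' header"
                )
            for tok in line.split():
                if tok[0] in "+-":
                    signs_seen = True
                    tok = tok[1:]
                if not tok:
                    raise InputFormatError(f"{origin}: bare strand sign")
                genes.append(tok)
    close()
    if not records:
        raise InputFormatError(f"{origin}: no gene-order records found")
    if signs_seen:
        logger.info(
            "%s: strand signs were present and discarded "
            "(TDRLs do not change strandedness)", origin,
        )
    return records


def parse_gene_order_file(path) -> list:
    """Parse a FASTA-like gene-order file; see :func:`parse_gene_order_text`."""
    p = Path(path)
    if not p.exists():
        raise InputFormatError(f"gene-order file not found: {p}")
    return parse_gene_order_text(p.read_text(), origin=str(p))


def relabel_by_target(
    source_rep: Sequence[Label], target_rep: Sequence[Label]
) -> tuple:
    """Positions (1-based) of the source's genes within the target.

    Reduces "transform source into target" to "sort w to the identity":
    ``w[i]`` is the position of ``source_rep[i]`` in ``target_rep``.  ``w``
    is the identity iff the two sequences are equal.
    """
    src, tgt = tuple(source_rep), tuple(target_rep)
    if set(src) != set(tgt) or len(src) != len(tgt):
        only_s = set(src) - set(tgt)
        only_t = set(tgt) - set(src)
        raise GeneSetMismatchError(
            f"element sets differ (only in source: {sorted(map(str, only_s))}, "
            f"only in target: {sorted(map(str, only_t))})"
        )
    pos = {g: i + 1 for i, g in enumerate(tgt)}
    return tuple(pos[g] for g in src)


@dataclass(frozen=True)
class ConservedSegment:
    """A maximal same-direction contiguous gene run shared by two orders."""

    genes: tuple

    @property
    def length(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _check_same_gene_set(a: CircularGeneOrder, b: CircularGeneOrder):
    if a.genes != b.genes:
        only_a = a.genes - b.genes
        only_b = b.genes - a.genes
        raise GeneSetMismatchError(
            f"gene sets differ (only in first: {sorted(map(str, only_a))}, "
            f"only in second: {sorted(map(str, only_b))})"
        )


def conserved_segments(
    a: CircularGeneOrder, b: CircularGeneOrder
) -> list:
    """All maximal common circular substrings (same reading direction).

    An adjacency x->y is conserved iff y follows x in both orders; the
    segments are the chains of conserved adjacencies.  They partition the
    gene set, singletons included, and are returned in the order their
    first gene appears along ``a``'s canonical rotation.  Identical orders
    yield a single segment covering the whole circle.
    """
    _check_same_gene_set(a, b)
    ra, rb = a.canonical, b.canonical
    n = a.n
    succ_a = {ra[i]: ra[(i + 1) % n] for i in range(n)}
    succ_b = {rb[i]: rb[(i + 1) % n] for i in range(n)}
    conserved = {g for g in ra if succ_a[g] == succ_b[g]}
    if len(conserved) == n:
        return [ConservedSegment(ra)]
    # segment starts: genes whose incoming adjacency is broken
    pred_a = {v: k for k, v in succ_a.items()}
    starts = [g for g in ra if pred_a[g] not in conserved]
    segments = []
    for s in starts:
        seg = [s]
        g = s
        while g in conserved:
            g = succ_a[g]
            seg.append(g)
        segments.append(ConservedSegment(tuple(seg)))
    return segments


def project_to_shared(
    a: GeneOrder, b: GeneOrder
) -> tuple:
    """Restrict both orders to their common gene set (with a warning).

    Supports comparing genomes annotated with slightly different marker
    sets; genes present in only one order are dropped, preserving the
    relative order of the rest.
    """
    shared = set(a.names) & set(b.names)
    if not shared:
        raise GeneSetMismatchError("orders share no genes")
    dropped = (set(a.names) | set(b.names)) - shared
    if dropped:
        logger.warning(
            "projecting to %d shared genes; dropped: %s",
            len(shared), sorted(map(str, dropped)),
        )
    return (
        GeneOrder([g for g in a.names if g in shared]),
        GeneOrder([g for g in b.names if g in shared]),
    )
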