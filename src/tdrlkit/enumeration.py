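"""Enumerate all equivalent TDRLs between circular orders at distance one.

Distinct triples can produce the same output order from the same input:
for a proper (non-identity) rearrangement of an n-gene circular order
there are exactly ``2n`` equivalent triples — two per origin, which are
F/S relabelings of each other — and ``2n^2`` when the map is the
identity.

The search is descent-based: fix an origin ``p`` and scan every
linearization of the target.  Writing that linearization as positions in
the origin representative, a triple exists iff the position sequence has
exactly one descent (cut F/S there); zero descents flags the identity
case, where every prefix cut is valid.  This is ``O(n^3)`` overall and
avoids the ``n * 2^n`` brute-force scan, which is kept as an independent
oracle for small ``n``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import DistanceExceededError, GeneSetMismatchError
from .distance import circular_tdrl_distance
from .orders import CircularGeneOrder
from .tdrl import PartialTdrl, Tdrl, apply_tdrl, minimal_partial

BRUTE_FORCE_MAX_N = 10

IDENTITY_CASE = "identity"
SINGLE_TDRL_CASE = "single-tdrl"


@dataclass
class EnumeratedTdrl:
    """One equivalent TDRL with its minimal window and annotation flags.

    ``labeling`` is ``"direct"`` when the origin gene keeps its second
    copy (the convention in which each origin's triple is usually quoted)
    and ``"swap"`` for the relabelled partner; ``displayed`` marks the
    labeling with the smaller minimal window, which a matrix rendering
    shows for its origin's row.
    """

    tdrl: Tdrl
    labeling: str  # "direct" | "swap" | "cut"
    partial: Optional[PartialTdrl]
    displayed: bool = False
    is_min_duplication: bool = False
    conserved_pass: dict = field(default_factory=dict)
    intergenic_pass: dict = field(default_factory=dict)

    @property
    def origin(self):
        return self.tdrl.origin

    @property
    def window_size(self) -> int:
        return self.partial.size if self.partial is not None else 0

    def passes_all_conserved(self) -> bool:
        return all(self.conserved_pass.values())

    def passes_all_intergenic(self) -> bool:
        return all(ok for ok, _ in self.intergenic_pass.values())


@dataclass
class EnumerationResult:
    """Complete set of equivalent TDRLs for one direction of an order pair."""

    source: CircularGeneOrder
    target: CircularGeneOrder
    direction: str
    case: str  # IDENTITY_CASE | SINGLE_TDRL_CASE
    entries: list

    @property
    def n(self) -> int:
        return self.source.n

    def by_origin(self) -> dict:
        out: dict = {}
        for e in self.entries:
            out.setdefault(e.origin, []).append(e)
        return out

    def triples(self) -> set:
        return {e.tdrl for e in self.entries}


def _pick_displayed(entries: list) -> None:
    """Mark, per origin, the labeling with the smaller minimal window.

    Ties break toward the smaller kept-first set, then lexicographically.
    """
    def sort_key(e: EnumeratedTdrl):
        return (
            e.window_size,
            len(e.tdrl.first),
            sorted(map(str, e.tdrl.first)),
        )

    best = min(entries, key=sort_key)
    for e in entries:
        e.displayed = e is best


def enumerate_equivalent_tdrls(
    source: CircularGeneOrder, target: CircularGeneOrder, direction: str = "a2b"
) -> EnumerationResult:
    """All triples ``(F, S, p)`` whose action maps ``source`` to ``target``.

    Requires the pair to differ by at most one TDRL.  In the single-TDRL
    case every origin contributes exactly two triples (F/S relabelings of
    each other): ``2n`` in total, each with its minimal partial window.
    In the identity case all ``2n^2`` order-fixing triples are returned,
    including the empty-F and empty-S prefix cuts.  Output order is
    deterministic: origins along the source's canonical rotation, the
    direct labeling before the swap.
    """
    if source.genes != target.genes:
        raise GeneSetMismatchError(
            f"gene sets differ: {sorted(map(str, source.genes ^ target.genes))}"
        )
    d = circular_tdrl_distance(source, target)
    if d > 1:
        raise DistanceExceededError(d, circular_tdrl_distance(target, source))
    case = IDENTITY_CASE if d == 0 else SINGLE_TDRL_CASE
    n = source.n
    target_reps = target.representatives()
    entries: list = []

    for p in source.canonical:
        pi_p = source.representative_starting_at(p)
        pos = {g: i for i, g in enumerate(pi_p)}
        origin_entries: list = []
        for sigma_q in target_reps:
            w = [pos[g] for g in sigma_q]
            descents = [i for i in range(n - 1) if w[i] > w[i + 1]]
            if len(descents) > 1:
                continue
            if not descents:
                # sigma_q == pi_p: identity map; every prefix cut fixes it
                for c in range(n + 1):
                    t = Tdrl(frozenset(pi_p[:c]), frozenset(pi_p[c:]), p)
                    origin_entries.append(
                        EnumeratedTdrl(tdrl=t, labeling="cut", partial=None)
                    )
            else:
                cut = descents[0] + 1
                t = Tdrl(frozenset(sigma_q[:cut]), frozenset(sigma_q[cut:]), p)
                labeling = "direct" if p in t.second else "swap"
                origin_entries.append(
                    EnumeratedTdrl(
                        tdrl=t,
                        labeling=labeling,
                        partial=minimal_partial(t, source) if case == SINGLE_TDRL_CASE else None,
                    )
                )
        if case == SINGLE_TDRL_CASE:
            origin_entries.sort(key=lambda e: e.labeling != "direct")
            _pick_displayed(origin_entries)
        else:
            origin_entries.sort(
                key=lambda e: (len(e.tdrl.first), sorted(map(str, e.tdrl.first)))
            )
        entries.extend(origin_entries)

    # sanity: the counting laws are structural, enforce them
    expected = 2 * n * n if case == IDENTITY_CASE else 2 * n
    seen = {e.tdrl for e in entries}
    assert len(entries) == len(seen) == expected, (
        f"enumeration produced {len(entries)} entries ({len(seen)} distinct), "
        f"expected {expected}"
    )
    return EnumerationResult(source, target, direction, case, entries)


def brute_force_enumerate(
    source: CircularGeneOrder, target: CircularGeneOrder
) -> list:
    """Oracle: test all ``n * 2^n`` triples by applying each one.

    Returns every triple whose output equals ``target`` (empty when the
    pair is at distance two or more).  Guarded to small ``n``.
    """
    n = source.n
    if n > BRUTE_FORCE_MAX_N:
        raise ValueError(
            f"n = {n} exceeds the brute-force guard ({BRUTE_FORCE_MAX_N})"
        )
    if source.genes != target.genes:
        raise GeneSetMismatchError("gene sets differ")
    found = []
    for p in source.canonical:
        rep = source.representative_starting_at(p)
        for mask in range(1 << n):
            f = frozenset(rep[i] for i in range(n) if mask >> i & 1)
            s = frozenset(rep[i] for i in range(n) if not mask >> i & 1)
            t = Tdrl(f, s, p)
            if apply_tdrl(t, source) == target:
                found.append(t)
    return found


def minimum_duplication_set(result: EnumerationResult) -> list:
    """Flag and return the TDRLs duplicating the fewest genes.

    Each origin's cost is the smaller of its two labelings' minimal
    windows; entries attaining the global minimum get
    ``is_min_duplication`` set.
    """
    if result.case == IDENTITY_CASE:
        raise ValueError(
            "identity case: every TDRL duplicates zero genes effectively"
        )
    global_min = min(e.window_size for e in result.entries)
    winners = []
    for e in result.entries:
        e.is_min_duplication = e.window_size == global_min
        if e.is_min_duplication:
            winners.append(e)
    return winners
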