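"""Biological constraint filters over enumerated TDRLs.

Two conditions narrow the set of equivalent TDRLs to the plausible ones:

* **Conserved gene groups** — genes known to travel together (e.g., one
  transcript).  A TDRL respects a group ``G`` iff ``G`` lies entirely in
  ``F`` or entirely in ``S``: then the whole group is lost from the same
  copy and the rearrangement never breaks it apart.

* **Intergenic pairs** — an ordered gene pair ``(x, y)`` framing an
  unannotated region of the *target* genome, suspected to be the remnant
  of an incompletely deleted gene.  A TDRL can explain the remnant iff
  some third gene ``z`` has a lost copy between ``x`` and ``y``:
  positions are taken in the origin representative; when ``x`` and ``y``
  sit in the same kept-set a gene of the opposite set must lie strictly
  between them, and when they sit in different sets any gene strictly
  between them has a lost copy there.

Both verdicts are invariant under interchanging ``F`` and ``S``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Optional, Sequence

from .errors import InputFormatError
from .enumeration import EnumerationResult
from .orders import CircularGeneOrder
from .tdrl import Tdrl

logger = logging.getLogger(__name__)

Label = Hashable


@dataclass(frozen=True)
class ConservedGroup:
    """A set of genes that one TDRL must not scatter."""

    genes: frozenset
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.label:
            object.__setattr__(
                self, "label", " ".join(sorted(map(str, self.genes)))
            )


@dataclass(frozen=True)
class IntergenicPair:
    """Ordered gene pair framing an intergenic region of the target."""

    x: Label
    y: Label

    def __post_init__(self):
        if self.x == self.y:
            raise InputFormatError(
                f"intergenic pair needs two distinct genes, got {self.x!r} twice"
            )

    @property
    def label(self) -> str:
        return f"{self.x},{self.y}"


def _check_genes_known(genes, order: CircularGeneOrder, what: str):
    for g in genes:
        if g not in order:
            raise InputFormatError(f"unknown gene {g!r} in {what}")


def passes_conserved_groups(
    t: Tdrl, groups: Sequence[ConservedGroup]
) -> tuple:
    """``(verdict, violating_groups)``: every group inside F or inside S?"""
    violating = []
    gene_set = t.genes
    for g in groups:
        unknown = g.genes - gene_set
        if unknown:
            raise InputFormatError(
                f"unknown gene {sorted(map(str, unknown))[0]!r} "
                f"in conserved group {g.label!r}"
            )
        if not (g.genes <= t.first or g.genes <= t.second):
            violating.append(g)
    return not violating, violating


def passes_intergenic_pair(
    t: Tdrl, source: CircularGeneOrder, pair: IntergenicPair
) -> tuple:
    """``(verdict, witness)``: can ``t`` explain a remnant between x and y?

    Betweenness is positional in the origin representative.  The witness
    is the first qualifying gene ``z`` (one whose lost copy falls between
    the kept copies of ``x`` and ``y``), or None.
    """
    _check_genes_known((pair.x, pair.y), source, f"intergenic pair {pair.label}")
    rep = source.representative_starting_at(t.origin)
    pos = {g: i for i, g in enumerate(rep)}
    i, j = sorted((pos[pair.x], pos[pair.y]))
    between = rep[i + 1 : j]
    same_set = (pair.x in t.first) == (pair.y in t.first)
    if same_set:
        opposite = t.second if pair.x in t.first else t.first
        witness = next((z for z in between if z in opposite), None)
    else:
        # x and y keep different copies: any gene between them loses a
        # copy inside the stretch separating the kept occurrences
        witness = between[0] if between else None
    return witness is not None, witness


def annotate_constraints(
    result: EnumerationResult,
    groups: Sequence[ConservedGroup] = (),
    pairs: Sequence[IntergenicPair] = (),
) -> EnumerationResult:
    """Evaluate all filters on every enumerated TDRL, in place.

    Fills ``conserved_pass`` (group label -> bool) and ``intergenic_pass``
    (pair label -> (bool, witness)) on each entry.  A warning is emitted
    for pairs that are not adjacent in the target order — they should
    frame an intergenic region there — but the filter still evaluates.
    """
    for pair in pairs:
        _check_genes_known((pair.x, pair.y), result.target, f"pair {pair.label}")
        succ = result.target.representative_starting_at(pair.x)
        if succ[1 % result.n] != pair.y:
            logger.warning(
                "intergenic pair (%s, %s) is not an adjacency of the target "
                "order; evaluating anyway", pair.x, pair.y,
            )
    for e in result.entries:
        ok, violating = passes_conserved_groups(e.tdrl, groups)
        e.conserved_pass = {g.label: g not in violating for g in groups}
        e.intergenic_pass = {
            p.label: passes_intergenic_pair(e.tdrl, result.source, p)
            for p in pairs
        }
    return result


def filter_passing(
    result: EnumerationResult,
    require_conserved: bool = True,
    require_intergenic: bool = True,
) -> list:
    """Entries passing every annotated filter of the requested kinds."""
    out = []
    for e in result.entries:
        if require_conserved and not e.passes_all_conserved():
            continue
        if require_intergenic and not e.passes_all_intergenic():
            continue
        out.append(e)
    return out


def parse_conserved_groups_file(path) -> list:
    """One group per line: whitespace-separated gene names; ``#`` comments."""
    p = Path(path)
    if not p.exists():
        raise InputFormatError(f"conserved-groups file not found: {p}")
    groups = []
    for raw in p.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        genes = line.split()
        if len(genes) < 2:
            logger.warning(
                "%s: singleton conserved group %r always passes", p, line
            )
        groups.append(ConservedGroup(frozenset(genes)))
    if not groups:
        raise InputFormatError(f"{p}: no conserved groups found")
    return groups


def parse_intergenic_pairs_file(path) -> list:
    """Two gene names per line, reading direction x -> y in the target."""
    p = Path(path)
    if not p.exists():
        raise InputFormatError(f"intergenic-pairs file not found: {p}")
    pairs = []
    for raw in p.read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        toks = line.split()
        if len(toks) != 2:
            raise InputFormatError(
                f"{p}: expected two gene names per line, got {line!r}"
            )
        pairs.append(IntergenicPair(toks[0], toks[1]))
    if not pairs:
        raise InputFormatError(f"{p}: no intergenic pairs found")
    return pairs
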