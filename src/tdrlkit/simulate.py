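"""Seeded synthetic gene orders and distance-one pairs.

Pure functions of ``(parameters, seed)``; they power the property tests
and the ``tdrlkit simulate`` command.  A random circular order is drawn
uniformly over rotation classes (a uniform permutation projects uniformly
onto its class, every class holding exactly ``n`` representatives).  A
distance-one pair applies a uniformly drawn non-identity TDRL — origin
uniform over genes, each gene assigned to F with probability 1/2,
identity maps rejected — so the generating event is always recoverable
from the enumeration and the pair's distance is exactly one.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .orders import CircularGeneOrder
from .tdrl import Tdrl, apply_tdrl, is_identity_tdrl


@dataclass(frozen=True)
class SyntheticPair:
    """A seeded order pair one known TDRL apart."""

    source: CircularGeneOrder
    target: CircularGeneOrder
    generating: Tdrl
    seed: int
    n: int


def random_circular_order(n: int, seed: int) -> CircularGeneOrder:
    """Uniformly random rotation class on genes ``1..n``; reproducible."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rng = random.Random(("order", n, seed).__repr__())
    perm = list(range(1, n + 1))
    rng.shuffle(perm)
    return CircularGeneOrder(perm)


def random_tdrl(
    order: CircularGeneOrder, seed: int, allow_identity: bool = False
) -> Tdrl:
    """A random TDRL on ``order``; identity maps rejected by default."""
    rng = random.Random(("tdrl", order.canonical, seed).__repr__())
    genes = order.canonical
    for _ in range(1000):
        origin = rng.choice(genes)
        first = frozenset(g for g in genes if rng.random() < 0.5)
        t = Tdrl(first, frozenset(genes) - first, origin)
        if allow_identity or not is_identity_tdrl(t, order):
            return t
    raise RuntimeError("rejection sampling failed to find a non-identity TDRL")


def random_d1_pair(n: int, seed: int) -> SyntheticPair:
    """A seeded pair of circular orders at TDRL distance exactly one."""
    if n < 4:
        raise ValueError(f"need n >= 4 for a robust non-identity pair, got {n}")
    source = random_circular_order(n, seed)
    t = random_tdrl(source, seed)
    target = apply_tdrl(t, source)
    assert target != source
    return SyntheticPair(source, target, t, seed, n)


def identity_pair(n: int, seed: int) -> SyntheticPair:
    """A seeded order paired with itself under a random identity TDRL.

    Exercises the ``2n^2`` counting law for identity maps.
    """
    source = random_circular_order(n, seed)
    rng = random.Random(("idcut", n, seed).__repr__())
    p = rng.choice(source.canonical)
    rep = source.representative_starting_at(p)
    c = rng.randint(0, n)
    t = Tdrl(frozenset(rep[:c]), frozenset(rep[c:]), p)
    return SyntheticPair(source, source, t, seed, n)


def write_pair_fasta(pair: SyntheticPair, path) -> None:
    """FASTA-like pair file: two records, source then target."""
    with open(path, "w") as fh:
        fh.write(">source\n" + " ".join(map(str, pair.source.canonical)) + "\n")
        fh.write(">target\n" + " ".join(map(str, pair.target.canonical)) + "\n")


def write_generating_tdrl_tsv(pair: SyntheticPair, path) -> None:
    """Sidecar record of the generating TDRL, for regression tests."""
    t = pair.generating
    with open(path, "w") as fh:
        fh.write("n\tseed\torigin\tF\tS\n")
        fh.write(
            f"{pair.n}\t{pair.seed}\t{t.origin}\t"
            + ",".join(map(str, sorted(t.first)))
            + "\t"
            + ",".join(map(str, sorted(t.second)))
            + "\n"
        )
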