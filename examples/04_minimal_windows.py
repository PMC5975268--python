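"""Minimal partial duplications and the minimum-duplication TDRLs.

Every whole-genome TDRL is equivalent to a partial duplication of a
contiguous window; the smallest window runs from the first second-copy
gene to the last first-copy gene of the origin representative.  TDRLs
that duplicate the fewest genes are the biologically cheapest candidates.
"""

from tdrlkit import (
    CircularGeneOrder,
    Tdrl,
    enumerate_equivalent_tdrls,
    minimal_partial,
    minimum_duplication_set,
    whole_from_partial,
)

source = CircularGeneOrder(range(1, 9))
target = CircularGeneOrder((1, 2, 4, 6, 3, 5, 7, 8))

t = Tdrl(frozenset({4, 6}), frozenset({1, 2, 3, 5, 7, 8}), 3)
part = minimal_partial(t, source)
print(f"TDRL {t} only needs to duplicate {part.window}:")
print(f"  kept in first copy:  {part.kept_first}")
print(f"  kept in second copy: {part.kept_second}")
print(f"  untouched:           {sorted(part.not_duplicated)}")
print(f"equivalent whole-genome triple: {whole_from_partial(part, source)}")
print()

result = enumerate_equivalent_tdrls(source, target)
winners = minimum_duplication_set(result)
print(
    f"minimum duplication: {winners[0].window_size} genes, attained at "
    f"origins {sorted({e.origin for e in winners})}"
)
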