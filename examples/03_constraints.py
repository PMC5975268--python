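"""Filter equivalent TDRLs by biological side information.

Conserved gene groups must survive in one copy (the event never splits
them); an intergenic region between two genes of the derived order is
explainable only by a TDRL that lost some gene between them — the lost
gene's remnant is what the intergenic DNA would be.
"""

from tdrlkit import (
    CircularGeneOrder,
    ConservedGroup,
    IntergenicPair,
    annotate_constraints,
    enumerate_equivalent_tdrls,
)

source = CircularGeneOrder(range(1, 9))
target = CircularGeneOrder((1, 2, 4, 6, 3, 5, 7, 8))
result = enumerate_equivalent_tdrls(source, target)

annotate_constraints(
    result,
    groups=[ConservedGroup(frozenset({1, 2})), ConservedGroup(frozenset({7, 8}))],
    pairs=[IntergenicPair(1, 2)],
)

keep_groups = sorted({e.origin for e in result.entries if e.passes_all_conserved()})
print(f"origins preserving groups {{1,2}} and {{7,8}}: {keep_groups}")
print("  (origins 2 and 8 would split a group between the two copies)")

explain = [e for e in result.entries if e.intergenic_pass["1,2"][0]]
origins = sorted({e.origin for e in explain})
witness = explain[0].intergenic_pass["1,2"][1]
print(f"origins explaining an intergenic region between 1 and 2: {origins}")
print(f"  witness: gene {witness} is lost between them in that intermediate")
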