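"""Enumerate every TDRL that explains a distance-one pair.

A single observed rearrangement never pins down the event: for n genes
there are exactly 2n equivalent triples (F, S, p) — two per origin gene,
which are relabelings of each other.  The text matrix shows, per origin
(row) and gene (column), which copy survives (o = first, x = second) and
boxes the minimal duplicated window.
"""

from tdrlkit import CircularGeneOrder, enumerate_equivalent_tdrls, render_text

source = CircularGeneOrder(range(1, 9))
target = CircularGeneOrder((1, 2, 4, 6, 3, 5, 7, 8))

result = enumerate_equivalent_tdrls(source, target)
print(f"{len(result.entries)} equivalent TDRLs (2n for n = {result.n}):")
for e in result.entries:
    if e.labeling == "direct":
        t = e.tdrl
        print(
            f"  origin {t.origin}: F = {sorted(t.first)}, "
            f"S = {sorted(t.second)}"
        )
print()
print(render_text(result))
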