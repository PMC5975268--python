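"""TDRL distances between two circular gene orders.

The distance is directional: sorting back can take more events than the
single duplication-loss that separated the pair.
"""

from tdrlkit import CircularGeneOrder, distance_both_directions

source = CircularGeneOrder(range(1, 9))
target = CircularGeneOrder((1, 2, 4, 6, 3, 5, 7, 8))

d_fwd, d_back = distance_both_directions(source, target)
print(f"source: {source.canonical}")
print(f"target: {target.canonical}")
print(f"d(source -> target) = {d_fwd}   # one TDRL explains the change")
print(f"d(target -> source) = {d_back}   # undoing it needs two events")
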