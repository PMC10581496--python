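"""Relation faces and overlap combinatorics on schematic purview sets.

Relations bind distinctions whose purviews overlap congruently (same units,
same states). Every selection of cause/effect purviews with a common
intersection is a face; a pair of distinctions can carry up to 3^2 = 9 faces.
"""

from phistruct.mechanisms import Distinction
from phistruct.relations import compute_relations, enumerate_faces


def distinction(cause, effect, phi=1.0):
    cause, effect = frozenset(cause), frozenset(effect)
    return Distinction(1, frozenset({(0, 0)}), 0, cause, 0, effect, phi, phi, phi)


# two distinctions whose four purviews all share unit b (OFF)
b = (1, 0)
d1 = distinction({b, (0, 0)}, {b, (2, 0)})
d2 = distinction({b, (3, 0)}, {b, (4, 0)})
print("purviews all sharing unit b:", len(enumerate_faces([d1, d2])), "faces")

# overlap only cause-to-cause: a single face
d3 = distinction({b}, {(2, 0)})
d4 = distinction({b}, {(4, 0)})
print("cause-to-cause overlap only:", len(enumerate_faces([d3, d4])), "faces")

# six effect purviews {a},{b},{c},{ab},{bc},{abc}: count related subsets
a, c = (0, 0), (2, 0)
effects = [{a}, {b}, {c}, {a, b}, {b, c}, {a, b, c}]
ds = [distinction({(10 + i, 0)}, e) for i, e in enumerate(effects)]
by_degree = {}
for r in compute_relations(ds):
    by_degree[r.degree] = by_degree.get(r.degree, 0) + 1
print("relations among the six effect purviews, by degree:", by_degree)
# 10 pairs, 6 triples and 1 quadruple share a congruent unit: the purview
# lattice binds the effects into a sequentially ordered structure.
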