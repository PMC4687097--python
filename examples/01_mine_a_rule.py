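"""Mine one transformation rule from a reactant-product pair.

Walks the full extraction path on the antipyrine -> 3-hydroxymethylantipyrine
CYP reaction: type both molecules, align them atom by atom, locate the
reaction center, and read off the look-up key and transformation value.
"""

from proximal.alignment import alignment_tsv, max_common_subgraph
from proximal.atom_typing import type_map
from proximal.fixtures import fixture_graph
from proximal.table_builder import ReactionRecord, extract_rule, find_reaction_centers

reactant = fixture_graph("antipyrine")
product = fixture_graph("hydroxymethylantipyrine")
rt, pt = type_map(reactant), type_map(product)

alignment = max_common_subgraph(reactant, product)
print(f"aligned {alignment.score} of {reactant.n_atoms} reactant atoms:\n")
print(alignment_tsv(alignment, rt, pt))

centers = find_reaction_centers(alignment, rt, pt)
(center,) = centers
print(f"reaction center: atom {center} "
      f"({rt[center]} in the reactant -> {pt[alignment.reactant_to_product()[center]]} in the product)")

record = ReactionRecord("example", ("1A2",), "I", reactant, product)
key, rule = extract_rule(record, center, alignment)
print(f"\nlook-up key:   center {key.rc_type}; adjacent {key.adjacent_types}; "
      f"distant {key.distant_types}")
print(f"value:         center becomes {rule.product_rc_type}; "
      f"adds {[el for _, el, _ in rule.added_atoms]} bonded at the center")
# The key is the two-level neighbourhood the matcher will look for in a
# query; the value is the edit script it will replay there.
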