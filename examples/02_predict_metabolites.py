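"""Predict Phase I/II metabolites of bisphenol A with the curated tables.

Every heavy atom of the query is a candidate reaction center; symmetric
sites (equal two-level keys) collapse, matched rules are replayed, and
Phase II conjugations chain onto Phase I products.
"""

from proximal.fixtures import curated_tables, fixture_graph
from proximal.transformer import enumerate_sites, predict

bpa = fixture_graph("bisphenol_a")
sites = enumerate_sites(bpa)
classes = len({s.symmetry_class for s in sites})
print(f"bisphenol A: {len(sites)} candidate substructures, {classes} unique after symmetry\n")

tables = curated_tables()
products = predict(bpa, tables.phase_i, tables.phase_ii, depth=2)
print(f"{len(products)} predicted metabolites:")
for p in products:
    print(f"  {'+'.join(p.phase_chain):5s} via site {p.site.atom_index:>2d} "
          f"({';'.join(sorted(p.enzymes))}): {p.canonical}")
# 'I' rows are CYP functionalisations (hydroxylation, epoxidation, carbonyl
# formation); 'II' rows are conjugates of the parent; 'I+II' rows are
# conjugates of a Phase I product, e.g. the glutathione adduct of the epoxide.
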