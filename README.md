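# proximal

Prediction of Phase I/II xenobiotic biotransformation products, with
CYP-based ranking.

When a foreign chemical — a drug, a plasticizer such as bisphenol A, a
pollutant such as 4-chlorobiphenyl — enters the liver, Phase I enzymes
(mostly cytochrome P450s) functionalise it and Phase II transferases
conjugate the result with glucuronide, sulfate, glutathione, methyl or
acetyl groups. The derivatives can be more bioactive than the parent, so
predicting *which* metabolites can form, and which are likely, matters for
toxicology, drug development and environmental health.

`proximal` answers this with a data-mined, substructure-specific approach:

1. **Mine look-up tables.** Each known reactant→product reaction pair is
   aligned atom-by-atom (maximum connected common subgraph on
   element-labelled graphs). Every aligned atom whose KEGG-style atom type
   changes is a *reaction center*. For each center a key–value pair is
   stored: the key is the triple (center type, adjacent-neighbour type
   multiset, distant-neighbour type multiset — distant neighbours are two
   bonds out and always include the center); the value is a replayable edit
   script (bond rewrites, leaving groups, added fragment). Phase I and
   Phase II reactions go into separate tables.
2. **Generate candidates.** Every heavy atom of a query molecule is a
   candidate center. Sites with identical keys are symmetry-equivalent and
   collapse to one representative. Exact key matches retrieve rules, whose
   reactant-side templates are embedded into the query and replayed;
   Phase II conjugation chains onto Phase I products (depth 2 by default).
3. **Rank Phase I products.** Each product is scored by

   *score* = Σ<sub>k</sub> (average activity)<sub>k</sub> × (average abundance)<sub>k</sub>

   over the CYP subfamilies *k* that can catalyse its formation, using
   activity/abundance statistics for the nine major hepatic CYPs (1A2, 2A6,
   2B6, 2C8, 2C9, 2C19, 2D6, 2E1, 3A4) collated from published hepatocyte
   studies — imputed, min–max scaled per study (a′ = (a<sub>ij</sub> −
   a<sub>j,min</sub>)/(a<sub>j,max</sub> − a<sub>j,min</sub>)),
   quantile-normalised across studies, iterated to 0.1 % convergence, and
   sum-normalised. A pre-normalised table ships with the package.

The package ships curated exemplar reactions (mined into tables at import),
packaged molfiles of the case-study compounds, and a seeded synthetic
reaction generator used as a round-trip oracle; an importer surface
(`proximal build-tables`) accepts external reaction manifests for
full-database mining.

## Worked example

```python
from proximal import (fixture_graph, max_common_subgraph, type_map,
                      find_reaction_centers, extract_key)

r = fixture_graph("antipyrine")                 # 14 heavy atoms
p = fixture_graph("hydroxymethylantipyrine")    # its CYP metabolite
a = max_common_subgraph(r, p)                   # aligns all 14 atoms
rt, pt = type_map(r), type_map(p)
find_reaction_centers(a, rt, pt)                # -> [9]
extract_key(r, rt, 9)
# -> LookupKey(rc_type='C1a', adjacent_types=('C8y',),
#              distant_types=('C1a', 'C8x', 'N4y'))
```

Atom 9 is the pyrazolone ring methyl: a C1a (R–CH₃) carbon that becomes
C1b (R–CH₂–R) in the product because a hydroxyl is grafted onto it. The
key records its one adjacent neighbour (C8y) and the distant neighbours
(N4y, C8x, plus the center itself).

Running the case studies end to end:

```sh
$ proximal demo
bisphenol A: 17 candidate substructures, 7 unique after symmetry
4-chlorobiphenyl: 13 candidate substructures, 8 unique after symmetry
...
BPA Phase I ranking (score = sum of CYP activity x abundance):
   1. BPA_I_1    0.0395  1A1;1A2;1B1;3A4  (no data: 1A1,1B1)
   2. BPA_I_2    0.0361  1A2;2D6;2E1
   3. BPA_I_3    0.0317  2E1
```

Bisphenol A's 17 heavy atoms collapse to 7 unique substructures; the demo
regenerates its hydroxylated, epoxide, quinone-like carbonyl, glucuronide
and sulfate derivatives as structures, plus second-generation conjugates of
the Phase I products. The ranking says hydroxylation (four CYPs, two with
liver data) is the most likely Phase I route — e.g.
0.0414×0.0895 + 0.1506×0.2374 = 0.0395 for BPA_I_1.

Narrative scripts in `examples/` cover each capability: rule mining,
metabolite prediction, ranking, and the synthetic round-trip oracle.

## Command line

```sh
proximal build-tables --manifest reactions.tsv --out tables.json
proximal transform --mol query.mol --tables tables.json --phases I,II --depth 2 --out products/
proximal rank --products products/products.tsv --out ranked.tsv
proximal demo
```

## Layout

- `src/proximal/chem_io.py` — molfile/SMILES I/O, molecular-graph model, canonical identity
- `src/proximal/atom_typing.py` — KEGG-style atom typing (config-driven table in `data/atom_types.yaml`)
- `src/proximal/alignment.py` — connected MCS search + exhaustive oracle
- `src/proximal/table_builder.py` — reaction centers, keys, rule extraction, table assembly/serialisation
- `src/proximal/transformer.py` — site enumeration, symmetry classes, rule replay, chained prediction
- `src/proximal/ranking.py` — normalisation pipeline and CYP activity×abundance scoring
- `src/proximal/fixtures.py` — packaged molecules, curated exemplars, synthetic generator
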