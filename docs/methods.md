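# Methods

## The model

The predictor assumes that xenobiotic transformations are *local*: what an
enzyme does to a molecule is determined by the atom it attacks (the
reaction center) and the chemistry within two covalent bonds of it. A
transformation observed once on that neighbourhood is assumed replayable on
any other molecule presenting the same neighbourhood. Concretely, the
neighbourhood is encoded as a key with three fields — the center's atom
type, the multiset of types of its bonded (adjacent) neighbours, and the
multiset of types of the neighbours-of-neighbours (distant; the set always
includes the center itself, so the key distinguishes e.g. a methyl from a
methylene center even with equal surroundings). Matching is exact on all
three fields; there is no fuzzy or partial matching, which is what makes
the approach specific compared with generic rule systems, at the cost of
coverage limited to neighbourhoods seen during mining.

### Atom typing

Atoms are labelled with KEGG-style codes (element + environment: C1a =
R–CH₃, C8x/C8y = aromatic CH / substituted aromatic C, N4y = substituted
aromatic N, O1a = hydroxyl, X = any halogen, ...). The implementation is a
priority-ordered decision table (`data/atom_types.yaml`) over per-atom
features: element, aromaticity (RDKit's default model, which covers
exocyclic-carbonyl heteroaromatics such as the antipyrine pyrazolone),
ring membership, hydrogen count, heavy degree, and double-bond context.
The table covers the ~30 classes exercised by drug-like fixtures rather
than the full 68-class KEGG vocabulary; sp3 carbons partition purely by
heavy-neighbour count (C1a–C1d), so ring-sp3 subclasses are deliberately
folded in. Unmatched environments get the flagged fallback `<El>?`, and
any key containing a fallback is excluded from matching — ill-typed
neighbourhoods never match silently. New classes are added by editing the
YAML, not the code.

### Alignment

Reactant and product are aligned by a maximum **connected common induced
subgraph**: atoms pair only if elements match (types may differ — a type
change at an aligned pair is precisely what marks a reaction center), and
bond *presence* must agree on both sides while bond *orders* may differ
(otherwise every oxidation would break its own alignment). The search
builds the modular product of the two graphs and runs a branch-and-bound
maximum c-clique search with a connectivity constraint; among equal-size
maxima the lexicographically smallest pair list wins, making alignments
deterministic. A node budget (default 2×10⁶ expansions) degrades the
search to best-found-so-far on pathological inputs; the fixtures never get
near it. Induced semantics was chosen over subgraph-monomorphism because
it is the only choice under which both of the module's contracts hold
simultaneously (bond-presence preservation in both directions, and
symmetry of the alignment score in its arguments); it also matches the
association-graph construction used by classical chemical MCS tools. An
independent exhaustive oracle (`brute_force_mcs`, ≤12 atoms) enumerates
connected induced reactant subgraphs and tests embeddability with VF2; the
two implementations share no search code and are compared on thousands of
random molecule pairs in the tests.

### Rule extraction and replay

For each reaction center the stored value contains: a reactant-side
*template* (atoms with types, bonds with orders/aromaticity) rooted at the
center; bond-order rewrites as absolute product orders (0 = delete); atoms
removed (leaving groups, e.g. the methyl of an N-demethylation); and the
added fragment as an explicit subgraph with its attachment bonds.
Additions and removals must attach within the two-level neighbourhood or
the rule is rejected as non-local — the key encodes only two levels, so a
wider pattern could not be applied consistently. Bond-order rewrites,
however, may extend further: de-aromatising transforms (quinone imine
formation, phenol→dienone oxidation, arene epoxidation) shift ring bonds
three or more bonds from the center, and the template simply grows to
cover every changed bond (kept connected via shortest paths). This keeps
the central invariant: **applying a rule to its own source reactant
regenerates the source product**, checked at table-build time for every
rule, by graph-canonical-key equality.

Replay first *embeds* the template into the query, rooted at the matched
site: atoms must agree on element and type, aromatic template bonds match
aromatic query bonds (Kekulé orientation is ignored), non-aromatic bonds
match exactly. The embedding is a finer filter than the key — two rules
can share a key yet apply to disjoint queries (the quinone-imine rewrite
requires a para acylamino nitrogen in its template, so it embeds on
acetaminophen but not on bisphenol A). After editing, the structure is
re-sanitised; valence violations reject the single product, never the run,
and implicit hydrogens, aromaticity and types are recomputed. Where a
de-aromatised product admits several tautomeric double-bond placements,
the one implied by the source reaction's Kekulé structure is produced;
this tautomer-level ambiguity is inherent to constitution-only modelling.

### Symmetry and validation at representatives

Candidate sites with identical key tuples form one symmetry class and only
the lowest-indexed representative is transformed (bisphenol A: 17 atoms, 7
classes; 4-chlorobiphenyl: 13 atoms, 8 classes — note its two biphenyl
link carbons are key-equivalent without being automorphic, which is why
class identity is defined by keys, not graph automorphism). Because
key-equal sites need not be automorphic, a rule mined at a
non-representative twin could regenerate a regioisomer when replayed at
the representative; table building therefore validates each rule by
replaying it exactly where the transformer will — at the representative —
and drops rules that fail, with a diagnostic. Retained rules thus satisfy
"predict on the source reactant returns the source product" by
construction.

### Chaining

Default depth 2 mirrors hepatic metabolism: Phase I on the query, Phase II
on the query, and Phase II on each Phase I product (conjugates are
terminal). Re-applying Phase I to Phase I products is available via
`reapply_phase_i` for deeper functionalisation chains. Products are
deduplicated by canonical key (RDKit canonical SMILES of the stereo-free
heavy-atom graph) with enzyme sets merged across generation paths, and
output order is stable (chain, site, canonical key).

## Ranking

The score of a Phase I product sums average activity × average abundance
over its catalysing CYP subfamilies. Raw per-study data (activity in
pmol substrate/min/mg protein, abundance in pmol CYP/mg protein) are made
comparable by: imputing missing cells from row averages; min–max scaling
each study column to [0, 1]; quantile normalisation across studies (tied
values get the mean of the pooled reference over their tied ranks); and
re-estimating the imputed cells from row means of the normalised matrix,
iterating until the largest relative change over imputed entries falls
below 0.1 % (`tol=1e-3`, `max_iter=200`; non-convergence raises with the
residual). Converged row averages are divided by their sum so each kind
totals 1 over the nine-CYP panel. The packaged statistics table carries,
besides the averages, per-row min/max of the converged matrices as
descriptive metadata only — they are not used by the score and no
min ≤ avg ≤ max relation is asserted against the sum-normalised averages.
Scores are kept at full precision internally and reported rounded
half-even to 4 decimals; ranking is a stable descending sort with ordinal
ranks, so tied products keep input order with distinct consecutive ranks.
Enzymes absent from the panel (1A1, 1B1, 2C18, 3A5) contribute nothing and
are flagged in the output. Phase II conjugates are not scored (transferase
data are too sparse); they carry a null score.

Two numerical caveats are intentional. Quantile normalisation is exactly
idempotent only on tie-free matrices — with ties, the tie-averaged values
perturb the pooled reference on a second pass — so the idempotence
property is stated (and tested) for continuous data. Imputation recovery
is bounded, not exact: an imputed cell can shift a column's ranks by at
most the number of imputed cells in it, and one rank step moves a
quantile-normalised value by ≈ 1/(n_rows − 1); the recovery test on
multiplicative (row × study) structure uses exactly that analytic bound at
30 % masking.

## Fixtures and the synthetic generator

The curated look-up tables are not hand-encoded: twelve exemplar reactions
(packaged as reactant/product molfile pairs with enzyme annotations)
covering aromatic hydroxylation, epoxidation, hydroxyl→carbonyl oxidation,
quinone-imine formation, N-demethylation, glucuronidation, sulfation,
catechol methylation and epoxide glutathione conjugation are mined through
the regular pipeline at import time. Conjugate fragments (glucuronosyl,
sulfo, glutathionyl, acetyl, methyl) are explicit subgraphs in the fixture
code. Metabolite structures transcribed from figure-only sources commit to
chemically standard attachment positions; the hydroxylated bisphenol A
fixture places the new hydroxyl ortho to the existing phenol.

The synthetic generator samples small liver-relevant scaffolds
(substituted benzenes, phenols, anilines, N-methyl amines, catechols,
cyclohexenones) and applies one deterministic graph edit per record, with
ground truth attached. Edits are injected only at symmetry-class
representative sites, pinning the oracle to the transformer's own site
identity. It emulates single-step, constitution-level transformations on
neutral molecules; it does not model reaction frequencies, stereochemistry,
charge states, multi-step kinetics, or database-scale chemical diversity —
passing the round-trip suite shows the mining/replay machinery is exact on
its domain, not that real-database tables would be complete or correct.

## Problem sizes and defaults

Test and acceptance workloads are sized for a laptop-class single CPU: the
aligner is verified against the exhaustive oracle on 1000 random pairs of
3–9-atom molecules; the round-trip property runs on 200 synthetic
reactions; normalisation properties use seeded 9×6 matrices (the shape of
the packaged CYP panel). Fixture molecules span 7–29 heavy atoms. The MCS
node budget, imputation tolerance (0.1 %) and iteration cap are the
defaults discussed above.

## Known limitations

- Coverage equals the mined tables: neighbourhoods absent from the
  reaction set yield no predictions (the classic false-negative mode of
  specific rules).
- Two-level keys cannot distinguish some non-equivalent sites (the
  4-chlorobiphenyl link carbons, guaiacol's meta carbons); such sites are
  treated as one class by design, and rules that would be regiochemically
  ambiguous under that identification are dropped at build time.
- Constitution-only: no stereochemistry, tautomer preference, protonation
  states, or 3D/conformer effects; V2000 molfiles only.
- Ranking covers Phase I products against a fixed 9-CYP liver panel; no
  CYP induction/inhibition adjustment, and no Phase II ranking.
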