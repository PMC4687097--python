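"""Packaged molecules, curated reaction exemplars, and a synthetic generator.

Full-scale table mining requires reaction databases; for a self-contained,
fully testable pipeline this module provides three substitutes:

* packaged molfiles of the case-study compounds (bisphenol A,
  4-chlorobiphenyl, acetaminophen, antipyrine) and their metabolites;
* a curated set of exemplar reactions covering the classic Phase I / II
  transformation chemistry (aromatic hydroxylation, epoxidation,
  hydroxyl-to-carbonyl oxidation, N-demethylation, glucuronidation,
  sulfation, catechol methylation, glutathione conjugation), which is mined
  through the regular pipeline into curated look-up tables;
* a seeded generator of synthetic single-edit reaction pairs with ground
  truth attached, used as the round-trip oracle for the whole pipeline
  (mine a rule from a pair, re-apply it, recover the product).

Conjugate fragments (glucuronosyl, sulfo, glutathionyl, acetyl, methyl) are
encoded as explicit subgraphs, not hard-coded edits.
"""

from __future__ import annotations

import csv
import functools
import random
from dataclasses import dataclass
from importlib import resources
from typing import Callable

from .atom_typing import type_map
from .chem_io import Atom, Bond, MolecularGraph, from_smiles, read_molfile
from .table_builder import ReactionRecord, TableBuild, build_tables

__all__ = [
    "fixture_names",
    "fixture_graph",
    "load_curated_reactions",
    "curated_tables",
    "SyntheticEditSpec",
    "EDIT_KINDS",
    "generate_synthetic_reactions",
]


# ---------------------------------------------------------------------------
# packaged molecules
# ---------------------------------------------------------------------------


def fixture_names() -> list[str]:
    base = resources.files("proximal.data").joinpath("molfiles")
    return sorted(p.name[:-4] for p in base.iterdir() if p.name.endswith(".mol"))


@functools.lru_cache(maxsize=None)
def fixture_graph(name: str) -> MolecularGraph:
    """Load a packaged molfile by name (e.g. 'bisphenol_a')."""
    path = resources.files("proximal.data").joinpath(f"molfiles/{name}.mol")
    return read_molfile(path.read_text(), name=name, source_id=f"fixture:{name}")


def load_curated_reactions() -> list[ReactionRecord]:
    """The packaged exemplar reaction set (manifest: data/reactions.tsv)."""
    text = resources.files("proximal.data").joinpath("reactions.tsv").read_text()
    records = []
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        records.append(
            ReactionRecord(
                id=row["id"],
                enzymes=tuple(row["enzymes"].split(";")),
                phase=row["phase"],
                reactant=fixture_graph(row["reactant"]),
                product=fixture_graph(row["product"]),
                source="fixture",
                metadata={"description": row["description"]},
            )
        )
    return records


@functools.lru_cache(maxsize=1)
def curated_tables() -> TableBuild:
    """Phase I / Phase II look-up tables mined from the curated exemplars."""
    return build_tables(load_curated_reactions())


# ---------------------------------------------------------------------------
# graph-edit helpers (independent of the rule machinery, used as ground truth)
# ---------------------------------------------------------------------------


def _edited(
    g: MolecularGraph,
    remove: set[int] = frozenset(),
    orders: dict[tuple[int, int], int] | None = None,
    add_atoms: list[str] | None = None,
    add_bonds: list[tuple[int, int, int]] | None = None,
) -> MolecularGraph:
    """Return a sanitised copy of *g* with the given edits applied.

    ``add_bonds`` may reference new atoms by index n_atoms + k (1-based,
    in ``add_atoms`` order).
    """
    orders = orders or {}
    norm_orders = {(min(i, j), max(i, j)): o for (i, j), o in orders.items()}
    keep = [a for a in g.atoms if a.index not in remove]
    new_index = {a.index: k + 1 for k, a in enumerate(keep)}
    atoms = [Atom(index=new_index[a.index], element=a.element, formal_charge=a.formal_charge) for a in keep]
    bonds = []
    for b in g.bonds:
        if b.i in remove or b.j in remove:
            continue
        o = norm_orders.get(b.key(), None)
        if o == 0:
            continue
        bonds.append(
            Bond(new_index[b.i], new_index[b.j], o if o is not None else b.order,
                 b.aromatic if o is None else False)
        )
    offset = g.n_atoms
    frag_new = {}
    for k, el in enumerate(add_atoms or []):
        idx = len(atoms) + 1
        frag_new[offset + k + 1] = idx
        atoms.append(Atom(index=idx, element=el))
    for i, j, o in add_bonds or []:
        bonds.append(Bond(frag_new.get(i) or new_index[i], frag_new.get(j) or new_index[j], o))
    draft = MolecularGraph(atoms, bonds, name=g.name, source_id=g.source_id)
    return MolecularGraph.from_rdkit(draft.to_rdkit(sanitize=True), name=g.name, source_id=g.source_id)


def _six_ring_through(g: MolecularGraph, i: int, j: int) -> list[int]:
    """The 6-ring cycle [i, j, ...] traversed from the i-j bond."""
    mol = g.to_rdkit(sanitize=True)
    for ring in mol.GetRingInfo().AtomRings():
        ring1 = [a + 1 for a in ring]
        if len(ring1) == 6 and i in ring1 and j in ring1:
            k = ring1.index(i)
            cyc = ring1[k:] + ring1[:k]
            if cyc[1] != j:
                cyc = [cyc[0]] + cyc[:0:-1]
            assert cyc[1] == j
            return cyc
    raise ValueError(f"no 6-ring through bond ({i},{j})")


# conjugate fragments as explicit subgraphs: (elements, internal bonds 1-based)
FRAGMENTS: dict[str, tuple[list[str], list[tuple[int, int, int]]]] = {
    "hydroxyl": (["O"], []),
    "methyl": (["C"], []),
    "acetyl": (["C", "O", "C"], [(1, 2, 2), (1, 3, 1)]),
    "sulfo": (["S", "O", "O", "O"], [(1, 2, 2), (1, 3, 2), (1, 4, 1)]),
    "glucuronosyl": (
        ["C", "O", "C", "C", "O", "O", "C", "O", "C", "O", "C", "O"],
        [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 2), (4, 6, 1), (3, 7, 1),
         (7, 8, 1), (7, 9, 1), (9, 10, 1), (9, 11, 1), (11, 12, 1), (11, 1, 1)],
    ),
    "glutathionyl": (
        ["S", "C", "C", "N", "C", "O", "C", "C", "C", "N", "C", "O", "O",
         "C", "O", "N", "C", "C", "O", "O"],
        [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 6, 2), (5, 7, 1),
         (7, 8, 1), (8, 9, 1), (9, 10, 1), (9, 11, 1), (11, 12, 2), (11, 13, 1),
         (3, 14, 1), (14, 15, 2), (14, 16, 1), (16, 17, 1), (17, 18, 1),
         (18, 19, 2), (18, 20, 1)],
    ),
}


def _attach_fragment(g: MolecularGraph, anchor: int, fragment: str, order: int = 1) -> MolecularGraph:
    elements, internal = FRAGMENTS[fragment]
    off = g.n_atoms
    add_bonds = [(off + i, off + j, o) for i, j, o in internal]
    add_bonds.append((anchor, off + 1, order))
    return _edited(g, add_atoms=elements, add_bonds=add_bonds)


# ---------------------------------------------------------------------------
# synthetic edit kinds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticEditSpec:
    """One deterministic single-edit transformation kind."""

    kind: str
    phase: str
    enzymes: tuple[str, ...]  # labels sampled for generated records
    targets: Callable[[MolecularGraph, dict[int, str]], list]
    apply: Callable[[MolecularGraph, object], MolecularGraph]


def _aromatic_ch(g, types):
    return [i for i, t in types.items() if t == "C8x"]


def _aromatic_ch_bonds(g, types):
    return [
        (b.i, b.j)
        for b in g.bonds
        if b.aromatic and types[b.i] == "C8x" and types[b.j] == "C8x"
    ]


def _hydroxylate(g, target):
    return _attach_fragment(g, target, "hydroxyl")


def _epoxidize(g, target):
    i, j = target
    cyc = _six_ring_through(g, i, j)
    a1, a2, a3, a4, a5, a6 = cyc
    orders = {(a1, a2): 1, (a2, a3): 1, (a3, a4): 2, (a4, a5): 1, (a5, a6): 2, (a6, a1): 1}
    off = g.n_atoms
    return _edited(g, orders=orders, add_atoms=["O"], add_bonds=[(a1, off + 1, 1), (a2, off + 1, 1)])


def _demethylation_targets(element):
    def targets(g, types):
        out = []
        for a in g.atoms:
            if a.element != element:
                continue
            for n in g.neighbors(a.index):
                if types[n] == "C1a":
                    out.append((a.index, n))
        return out

    return targets


def _demethylate(g, target):
    _, methyl = target
    return _edited(g, remove={methyl})


def _phenol_oxygens(g, types):
    return [
        i
        for i, t in types.items()
        if t == "O1a" and any(types[n].startswith("C8") for n in g.neighbors(i))
    ]


def _hydroxyl_to_carbonyl(g, target):
    q = g.neighbors(target)[0]
    partner = next(
        n for n in g.neighbors(q)
        if n != target and (b := g.bond_between(q, n)).aromatic and b.order == 2
    )
    return _edited(g, orders={(target, q): 2, (q, partner): 1})


def _catechol_oxygens(g, types):
    out = []
    for i in _phenol_oxygens(g, types):
        (c,) = [n for n in g.neighbors(i)]
        for c2 in g.neighbors(c):
            if types.get(c2) == "C8y" and any(
                types[n] == "O1a" and n != i for n in g.neighbors(c2)
            ):
                out.append(i)
                break
    return out


def _primary_amines(g, types):
    return [i for i, t in types.items() if t == "N1a"]


def _enone_beta_carbons(g, types):
    out = []
    for b in g.bonds:
        if b.order != 2 or b.aromatic:
            continue
        for alpha, beta in ((b.i, b.j), (b.j, b.i)):
            if types[alpha] == "C2x" and types[beta] == "C2x":
                if any(types[n] == "C5a" for n in g.neighbors(alpha)):
                    out.append((alpha, beta))
    return out


def _gsh_conjugate(g, target):
    alpha, beta = target
    h = _edited(g, orders={(alpha, beta): 1})
    return _attach_fragment(h, beta, "glutathionyl")


EDIT_KINDS: dict[str, SyntheticEditSpec] = {
    s.kind: s
    for s in [
        SyntheticEditSpec(
            "aromatic_hydroxylation", "I", ("1A2", "2E1", "3A4", "2C9"),
            _aromatic_ch, _hydroxylate,
        ),
        SyntheticEditSpec(
            "epoxidation", "I", ("2E1", "3A4"), _aromatic_ch_bonds, _epoxidize
        ),
        SyntheticEditSpec(
            "o_demethylation", "I", ("2D6", "1A2"),
            _demethylation_targets("O"), _demethylate,
        ),
        SyntheticEditSpec(
            "n_demethylation", "I", ("3A4", "2D6"),
            _demethylation_targets("N"), _demethylate,
        ),
        SyntheticEditSpec(
            "hydroxyl_to_carbonyl", "I", ("2E1", "1A2"),
            _phenol_oxygens, _hydroxyl_to_carbonyl,
        ),
        SyntheticEditSpec(
            "glucuronidation", "II", ("UGT",),
            _phenol_oxygens, lambda g, t: _attach_fragment(g, t, "glucuronosyl"),
        ),
        SyntheticEditSpec(
            "sulfation", "II", ("SULT",),
            _phenol_oxygens, lambda g, t: _attach_fragment(g, t, "sulfo"),
        ),
        SyntheticEditSpec(
            "methylation", "II", ("COMT",),
            _catechol_oxygens, lambda g, t: _attach_fragment(g, t, "methyl"),
        ),
        SyntheticEditSpec(
            "glutathione_conjugation", "II", ("GST",),
            _enone_beta_carbons, _gsh_conjugate,
        ),
        SyntheticEditSpec(
            "acetylation", "II", ("NAT",),
            _primary_amines, lambda g, t: _attach_fragment(g, t, "acetyl"),
        ),
    ]
}

#: small liver-relevant scaffolds the generator samples from
SCAFFOLDS: tuple[tuple[str, str], ...] = (
    ("benzene", "c1ccccc1"),
    ("toluene", "Cc1ccccc1"),
    ("phenol", "Oc1ccccc1"),
    ("p-cresol", "Cc1ccc(O)cc1"),
    ("anisole", "COc1ccccc1"),
    ("4-methylanisole", "COc1ccc(C)cc1"),
    ("aniline", "Nc1ccccc1"),
    ("4-chloroaniline", "Nc1ccc(Cl)cc1"),
    ("N-methylaniline", "CNc1ccccc1"),
    ("N,N-dimethylaniline", "CN(C)c1ccccc1"),
    ("catechol", "Oc1ccccc1O"),
    ("4,5-dimethylcatechol", "Cc1cc(O)c(O)cc1C"),
    ("guaiacol", "COc1ccccc1O"),
    ("cyclohex-2-enone", "O=C1CCCC=C1"),
    ("4,4-dimethylcyclohex-2-enone", "CC1(C)CCC(=O)C=C1"),
)


def generate_synthetic_reactions(seed: int, n: int) -> list[ReactionRecord]:
    """Deterministically sample *n* single-edit reaction pairs.

    Each record carries ground-truth metadata (edit kind, target atoms) so
    tests can verify that table mining recovers the injected edit.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    from .transformer import enumerate_sites  # local import to avoid a cycle

    rng = random.Random(seed)
    records = []
    while len(records) < n:
        name, smi = SCAFFOLDS[rng.randrange(len(SCAFFOLDS))]
        g = from_smiles(smi, name=name)
        types = type_map(g)
        # edit only symmetry-class representatives: sites with equal keys are
        # interchangeable to the matcher, so ground truth is pinned to the
        # same representative the transformer will pick
        reps = {s.atom_index for s in enumerate_sites(g, types) if s.representative}

        def _rep(target) -> bool:
            atom = target if isinstance(target, int) else target[0]
            return atom in reps

        applicable = [
            (spec, kept)
            for spec in EDIT_KINDS.values()
            if (kept := [t for t in spec.targets(g, types) if _rep(t)])
        ]
        if not applicable:
            continue
        spec, targets = applicable[rng.randrange(len(applicable))]
        target = targets[rng.randrange(len(targets))]
        product = spec.apply(g, target)
        rid = f"SYN{len(records):04d}"
        records.append(
            ReactionRecord(
                id=rid,
                enzymes=(spec.enzymes[rng.randrange(len(spec.enzymes))],),
                phase=spec.phase,
                reactant=g,
                product=product,
                source="synthetic",
                metadata={"kind": spec.kind, "target": target, "scaffold": name},
            )
        )
    return records
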