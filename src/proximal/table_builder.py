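"""Mining transformation look-up tables from aligned reaction pairs.

Each reactant-product pair is aligned atom-by-atom; every aligned reactant
atom whose type differs from its product image is a *reaction center*.  For
each center a key-value pair is extracted:

* the **key** is the center's type plus the type multisets of its adjacent
  neighbours (one bond away) and distant neighbours (two bonds away; the
  distant set always includes the center itself);
* the **value** (:class:`TransformationRule`) stores everything needed to
  replay the transformation on another molecule: a rooted template of the
  reactant substructure, bond-order rewrites, atoms removed (leaving
  groups), and the added fragment with its attachment bonds.

Separate tables are kept for Phase I (functionalisation) and Phase II
(conjugation) reactions.  Rules whose additions or removals reach outside
the matched two-level substructure are rejected as non-local: the key only
encodes two levels, so such rules could not be applied consistently.
Bond-order rewrites may extend further (e.g. ring de-aromatisation on
quinone formation); the template simply grows to cover them, which keeps
the round-trip invariant: applying a rule to its own source reactant
regenerates the source product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable

import networkx as nx

from .alignment import AtomAlignment, max_common_subgraph
from .atom_typing import is_fallback_type, type_map
from .chem_io import MolecularGraph, canonical_key

__all__ = [
    "ReactionRecord",
    "LookupKey",
    "TransformationRule",
    "LookupTable",
    "TableBuild",
    "RuleExtractionError",
    "find_reaction_centers",
    "extract_key",
    "extract_rule",
    "build_tables",
    "save_tables",
    "load_tables",
    "normalize_enzyme",
]

SCHEMA_VERSION = 1

#: Phase II transferases by common abbreviation -> EC number.
PHASE_II_EC = {
    "UGT": "2.4.1.17",
    "SULT": "2.8.2.1",
    "NAT": "2.3.1.5",
    "GST": "2.5.1.18",
    "TPMT": "2.1.1.67",
    "COMT": "2.1.1.6",
}


class RuleExtractionError(ValueError):
    """A transformation could not be captured as a local rule."""


def normalize_enzyme(name: str, phase: str) -> str:
    """Normalise enzyme labels: CYPs to subfamily tokens, Phase II to EC numbers."""
    token = name.strip()
    if phase == "I":
        upper = token.upper()
        if upper.startswith("CYP"):
            upper = upper[3:]
        return upper
    return PHASE_II_EC.get(token.upper(), token)


@dataclass(frozen=True)
class ReactionRecord:
    """One reactant-product pair with enzyme annotation."""

    id: str
    enzymes: tuple[str, ...]
    phase: str  # "I" | "II"
    reactant: MolecularGraph
    product: MolecularGraph
    source: str = "fixture"  # fixture | synthetic | imported
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.phase not in ("I", "II"):
            raise ValueError(f"phase must be 'I' or 'II', got {self.phase!r}")
        if not self.enzymes:
            raise ValueError("enzyme annotation must be non-empty")


@dataclass(frozen=True, order=True)
class LookupKey:
    """Reaction-center type + sorted neighbour-type multisets (Fig-style key)."""

    rc_type: str
    adjacent_types: tuple[str, ...]
    distant_types: tuple[str, ...]

    def has_fallback(self) -> bool:
        return any(
            is_fallback_type(t)
            for t in (self.rc_type, *self.adjacent_types, *self.distant_types)
        )

    def as_str(self) -> str:
        return f"{self.rc_type}|{','.join(self.adjacent_types)}|{','.join(self.distant_types)}"

    @classmethod
    def from_str(cls, s: str) -> "LookupKey":
        rc, adj, dist = s.split("|")
        return cls(rc, tuple(adj.split(",")) if adj else (), tuple(dist.split(",")) if dist else ())


@dataclass(frozen=True)
class TransformationRule:
    """Replayable transformation at a matched reaction center.

    Template positions are local ids 0..m-1 with position 0 the reaction
    center.  ``bond_changes`` store absolute product bond orders (0 deletes
    the bond).  Added fragment atoms use their own local ids and attach to
    template positions.
    """

    product_rc_type: str
    product_adjacent_types: tuple[str, ...]
    # reactant-side substructure template
    template_atoms: tuple[tuple[int, str, str], ...]  # (pos, element, kegg_type)
    template_bonds: tuple[tuple[int, int, int, bool], ...]  # (pos_i, pos_j, order, aromatic)
    removed_positions: tuple[int, ...]
    bond_changes: tuple[tuple[int, int, int], ...]  # (pos_i, pos_j, new_order)
    added_atoms: tuple[tuple[int, str, int], ...]  # (frag_id, element, charge)
    added_bonds: tuple[tuple[int, int, int], ...]  # (frag_i, frag_j, order)
    attachments: tuple[tuple[int, int, int], ...]  # (pos, frag_id, order)
    enzymes: frozenset[str] = frozenset()
    phase: str = "I"
    provenance: tuple[str, ...] = ()

    def structural_signature(self) -> str:
        """Identity of the structural transformation (enzymes/provenance excluded)."""
        return json.dumps(
            {
                "prc": self.product_rc_type,
                "padj": self.product_adjacent_types,
                "ta": self.template_atoms,
                "tb": self.template_bonds,
                "rm": self.removed_positions,
                "bc": self.bond_changes,
                "aa": self.added_atoms,
                "ab": self.added_bonds,
                "at": self.attachments,
                "ph": self.phase,
            },
            sort_keys=True,
        )


@dataclass
class LookupTable:
    """Key -> transformation rules for one metabolic phase."""

    phase: str
    entries: dict[LookupKey, list[TransformationRule]] = field(default_factory=dict)

    def add(self, key: LookupKey, rule: TransformationRule) -> None:
        if rule.phase != self.phase:
            raise ValueError(f"rule phase {rule.phase} does not match table phase {self.phase}")
        rules = self.entries.setdefault(key, [])
        sig = rule.structural_signature()
        for k, existing in enumerate(rules):
            if existing.structural_signature() == sig:
                rules[k] = replace(
                    existing,
                    enzymes=existing.enzymes | rule.enzymes,
                    provenance=tuple(sorted(set(existing.provenance) | set(rule.provenance))),
                )
                return
        rules.append(rule)
        rules.sort(key=TransformationRule.structural_signature)

    @property
    def n_rules(self) -> int:
        return sum(len(v) for v in self.entries.values())

    def lookup(self, key: LookupKey) -> list[TransformationRule]:
        if key.has_fallback():
            return []
        return list(self.entries.get(key, []))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def find_reaction_centers(
    a: AtomAlignment, r_types: dict[int, str], p_types: dict[int, str]
) -> list[int]:
    """Aligned reactant atoms whose type differs from their product image."""
    return sorted(ri for ri, pi in a.pairs if r_types[ri] != p_types[pi])


def _neighborhood(g: MolecularGraph, center: int) -> tuple[list[int], list[int]]:
    adjacent = sorted(g.neighbors(center))
    distant = sorted(
        ({n for a in adjacent for n in g.neighbors(a)} - set(adjacent)) | {center}
    )
    return adjacent, distant


def extract_key(g: MolecularGraph, types: dict[int, str], center: int) -> LookupKey:
    """Two-level neighbourhood key at *center*.

    Adjacent neighbours are one bond away; distant neighbours are the
    neighbours of adjacent atoms, excluding the adjacent atoms themselves.
    The distant set always includes the center.
    """
    adjacent, distant = _neighborhood(g, center)
    return LookupKey(
        rc_type=types[center],
        adjacent_types=tuple(sorted(types[a] for a in adjacent)),
        distant_types=tuple(sorted(types[d] for d in distant)),
    )


def extract_rule(
    rec: ReactionRecord,
    center: int,
    a: AtomAlignment,
    r_types: dict[int, str] | None = None,
    p_types: dict[int, str] | None = None,
) -> tuple[LookupKey, TransformationRule]:
    """Extract the (key, value) pair for one reaction center.

    Raises :class:`RuleExtractionError` when the pattern is not local:
    added fragments or leaving groups attached outside the center's
    two-level neighbourhood cannot be encoded against a two-level key.
    """
    r, p = rec.reactant, rec.product
    if r_types is None:
        r_types = type_map(r)
    if p_types is None:
        p_types = type_map(p)
    fwd = a.reactant_to_product()
    if center not in fwd:
        raise RuleExtractionError(f"{rec.id}: atom {center} is not aligned")
    if r_types[center] == p_types[fwd[center]]:
        raise RuleExtractionError(f"{rec.id}: atom {center} is not a reaction center")

    adjacent, distant = _neighborhood(r, center)
    two_level = {center} | set(adjacent) | set(distant)
    key = extract_key(r, r_types, center)

    # bond-order rewrites between aligned atoms
    changed: list[tuple[int, int, int]] = []
    for b in r.bonds:
        if b.i not in fwd or b.j not in fwd:
            continue
        pb = p.bond_between(fwd[b.i], fwd[b.j])
        if pb is None:
            changed.append((b.i, b.j, 0))
            continue
        if b.aromatic and pb.aromatic:
            continue
        if b.order == pb.order and b.aromatic == pb.aromatic:
            continue
        changed.append((b.i, b.j, pb.order))

    # leaving groups: reactant atoms with no product image
    removed = sorted(at.index for at in r.atoms if at.index not in fwd)
    for rm in removed:
        aligned_nbrs = [n for n in r.neighbors(rm) if n in fwd]
        if any(n not in two_level for n in aligned_nbrs):
            raise RuleExtractionError(
                f"{rec.id}: removed atom {rm} attaches outside the two-level "
                f"neighbourhood of center {center} (pattern not local)"
            )

    # added fragment: product atoms with no reactant preimage
    back = a.product_to_reactant()
    added_p = sorted(at.index for at in p.atoms if at.index not in back)
    frag_id = {pa: k for k, pa in enumerate(added_p)}
    added_atoms = tuple(
        (frag_id[pa], p.atom(pa).element, p.atom(pa).formal_charge) for pa in added_p
    )
    added_bonds: list[tuple[int, int, int]] = []
    attachments_raw: list[tuple[int, int, int]] = []  # (reactant_atom, frag_id, order)
    for b in p.bonds:
        bi_new, bj_new = b.i in frag_id, b.j in frag_id
        if bi_new and bj_new:
            added_bonds.append((frag_id[b.i], frag_id[b.j], b.order))
        elif bi_new or bj_new:
            pa, qa = (b.i, b.j) if bi_new else (b.j, b.i)
            anchor = back[qa]
            if anchor not in two_level:
                raise RuleExtractionError(
                    f"{rec.id}: added fragment attaches at reactant atom {anchor}, "
                    f"outside the two-level neighbourhood of center {center}"
                )
            attachments_raw.append((anchor, frag_id[pa], b.order))

    # template: two-level neighbourhood grown to cover all edited atoms
    t_atoms = set(two_level) | set(removed)
    for i, j, _ in changed:
        t_atoms.update((i, j))
    rG = nx.Graph()
    rG.add_nodes_from(at.index for at in r.atoms)
    rG.add_edges_from((b.i, b.j) for b in r.bonds)
    comps = [c for c in nx.connected_components(rG.subgraph(t_atoms))]
    while len(comps) > 1:
        # connect the component containing the center to the nearest other one
        base = next(c for c in comps if center in c)
        best_path = None
        for other in comps:
            if other is base:
                continue
            for tgt in sorted(other):
                path = nx.shortest_path(rG, center, tgt)
                if best_path is None or len(path) < len(best_path):
                    best_path = path
        t_atoms.update(best_path)
        comps = [c for c in nx.connected_components(rG.subgraph(t_atoms))]

    order = [center] + sorted(t_atoms - {center})
    pos = {atom: k for k, atom in enumerate(order)}
    template_atoms = tuple(
        (pos[atom], r.atom(atom).element, r_types[atom]) for atom in order
    )
    template_bonds = tuple(
        sorted(
            (min(pos[b.i], pos[b.j]), max(pos[b.i], pos[b.j]), b.order, b.aromatic)
            for b in r.bonds
            if b.i in pos and b.j in pos
        )
    )
    removed_positions = tuple(sorted(pos[rm] for rm in removed))
    bond_changes = tuple(
        sorted((min(pos[i], pos[j]), max(pos[i], pos[j]), new) for i, j, new in changed)
    )
    attachments = tuple(sorted((pos[anchor], fid, o) for anchor, fid, o in attachments_raw))

    p_center = fwd[center]
    rule = TransformationRule(
        product_rc_type=p_types[p_center],
        product_adjacent_types=tuple(sorted(p_types[n] for n in p.neighbors(p_center))),
        template_atoms=template_atoms,
        template_bonds=template_bonds,
        removed_positions=removed_positions,
        bond_changes=bond_changes,
        added_atoms=added_atoms,
        added_bonds=tuple(sorted(added_bonds)),
        attachments=attachments,
        enzymes=frozenset(normalize_enzyme(e, rec.phase) for e in rec.enzymes),
        phase=rec.phase,
        provenance=(rec.id,),
    )
    return key, rule


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------


@dataclass
class TableBuild:
    phase_i: LookupTable
    phase_ii: LookupTable
    diagnostics: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter((self.phase_i, self.phase_ii))


def build_tables(records: Iterable[ReactionRecord], validate: bool = True) -> TableBuild:
    """Assemble Phase I and Phase II look-up tables from reaction records.

    Every record contributes one (key, rule) entry per reaction center.
    Rules that are non-local, carry fallback atom types, or fail the
    round-trip check (re-applying the rule to its own reactant must
    regenerate the product) are skipped with a diagnostic, never fatally.
    """
    from .transformer import replay_rule  # local import to avoid a cycle

    records = list(records)
    if not records:
        raise ValueError("no reaction records given")
    build = TableBuild(LookupTable("I"), LookupTable("II"))
    for rec in records:
        table = build.phase_i if rec.phase == "I" else build.phase_ii
        try:
            r_types = type_map(rec.reactant)
            p_types = type_map(rec.product)
            a = max_common_subgraph(rec.reactant, rec.product)
            centers = find_reaction_centers(a, r_types, p_types)
        except Exception as exc:
            build.diagnostics.append(f"{rec.id}: alignment failed: {exc}")
            continue
        if not centers:
            build.diagnostics.append(f"{rec.id}: no reaction center found")
            continue
        # symmetry-class representatives in the reactant: validation replays
        # each rule at the representative, exactly as the transformer will
        all_keys = {at.index: extract_key(rec.reactant, r_types, at.index) for at in rec.reactant.atoms}
        rep_of = {
            c: min(a for a, k in all_keys.items() if k == all_keys[c]) for c in centers
        }
        for center in centers:
            try:
                key, rule = extract_rule(rec, center, a, r_types, p_types)
            except RuleExtractionError as exc:
                build.diagnostics.append(str(exc))
                continue
            if key.has_fallback():
                build.diagnostics.append(
                    f"{rec.id}: key at center {center} contains a fallback type; skipped"
                )
                continue
            if validate:
                try:
                    regenerated = replay_rule(rec.reactant, rep_of[center], rule)
                except Exception as exc:
                    build.diagnostics.append(
                        f"{rec.id}: rule at center {center} failed to replay: {exc}"
                    )
                    continue
                if canonical_key(regenerated) != canonical_key(rec.product):
                    build.diagnostics.append(
                        f"{rec.id}: rule at center {center} does not round-trip at its "
                        f"symmetry representative {rep_of[center]}; skipped"
                    )
                    continue
            table.add(key, rule)
    return build


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _table_to_dict(t: LookupTable) -> dict:
    entries = []
    for key in sorted(t.entries):
        rules = sorted(t.entries[key], key=TransformationRule.structural_signature)
        entries.append(
            {
                "key": key.as_str(),
                "rules": [
                    {
                        "product_rc_type": r.product_rc_type,
                        "product_adjacent_types": list(r.product_adjacent_types),
                        "template_atoms": [list(x) for x in r.template_atoms],
                        "template_bonds": [list(x) for x in r.template_bonds],
                        "removed_positions": list(r.removed_positions),
                        "bond_changes": [list(x) for x in r.bond_changes],
                        "added_atoms": [list(x) for x in r.added_atoms],
                        "added_bonds": [list(x) for x in r.added_bonds],
                        "attachments": [list(x) for x in r.attachments],
                        "enzymes": sorted(r.enzymes),
                        "phase": r.phase,
                        "provenance": list(r.provenance),
                    }
                    for r in rules
                ],
            }
        )
    return {"phase": t.phase, "entries": entries}


def _table_from_dict(d: dict) -> LookupTable:
    t = LookupTable(d["phase"])
    for entry in d["entries"]:
        key = LookupKey.from_str(entry["key"])
        for rd in entry["rules"]:
            t.add(
                key,
                TransformationRule(
                    product_rc_type=rd["product_rc_type"],
                    product_adjacent_types=tuple(rd["product_adjacent_types"]),
                    template_atoms=tuple(tuple(x) for x in rd["template_atoms"]),
                    template_bonds=tuple(tuple(x) for x in rd["template_bonds"]),
                    removed_positions=tuple(rd["removed_positions"]),
                    bond_changes=tuple(tuple(x) for x in rd["bond_changes"]),
                    added_atoms=tuple(tuple(x) for x in rd["added_atoms"]),
                    added_bonds=tuple(tuple(x) for x in rd["added_bonds"]),
                    attachments=tuple(tuple(x) for x in rd["attachments"]),
                    enzymes=frozenset(rd["enzymes"]),
                    phase=rd["phase"],
                    provenance=tuple(rd["provenance"]),
                ),
            )
    return t


def save_tables(phase_i: LookupTable, phase_ii: LookupTable, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "phase_i": _table_to_dict(phase_i),
        "phase_ii": _table_to_dict(phase_ii),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_tables(path) -> tuple[LookupTable, LookupTable]:
    with open(path) as fh:
        doc = json.load(fh)
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported look-up table schema version {version!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    return _table_from_dict(doc["phase_i"]), _table_from_dict(doc["phase_ii"])
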