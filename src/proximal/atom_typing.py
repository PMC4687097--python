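"""KEGG-style atom typing.

Every heavy atom receives a short code (C1a, C8x, N4y, O1a, X, ...) that
encodes its element and local bonding environment.  The code table is the
vocabulary in which reaction centers and their neighbourhoods are expressed;
two atoms "look the same" to the pattern matcher exactly when their codes
agree.  Assignment is driven by a packaged, human-editable decision table
(``data/atom_types.yaml``) evaluated in priority order, so additional KEGG
classes can be added without code changes.

Atoms whose environment matches no rule get the flagged fallback type
``"<Element>?"``; keys containing a fallback type never participate in
look-up table matching.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import yaml

from .chem_io import MolecularGraph

__all__ = [
    "TypedAtom",
    "perceive_aromaticity",
    "assign_types",
    "type_map",
    "is_fallback_type",
    "load_type_table",
]


@dataclass(frozen=True)
class TypedAtom:
    index: int
    element: str
    kegg_type: str


def is_fallback_type(code: str) -> bool:
    return code.endswith("?")


@functools.lru_cache(maxsize=1)
def load_type_table() -> tuple[dict, ...]:
    """Load the packaged decision table (priority = file order)."""
    text = resources.files("proximal.data").joinpath("atom_types.yaml").read_text()
    doc = yaml.safe_load(text)
    return tuple(doc["rules"])


def perceive_aromaticity(g: MolecularGraph) -> MolecularGraph:
    """Return a copy of *g* with aromatic flags re-perceived.

    Delegates to RDKit's default aromaticity model, which flags rings that
    satisfy a Hueckel-style alternation test (including exocyclic-carbonyl
    heteroaromatics such as pyrazolones).  Deterministic and idempotent.
    """
    mol = g.to_rdkit(sanitize=True)  # sanitization perceives aromaticity
    return MolecularGraph.from_rdkit(mol, name=g.name, source_id=g.source_id)


@dataclass(frozen=True)
class _AtomEnv:
    element: str
    aromatic: bool
    in_ring: bool
    h: int
    heavy_degree: int
    unsaturated: bool
    double_to: frozenset[str]
    double_to_aromatic: bool
    carboxyl_self: bool
    carboxyl_neighbor: bool


def _environments(g: MolecularGraph) -> list[_AtomEnv]:
    mol = g.to_rdkit(sanitize=True)
    ring_info = mol.GetRingInfo()
    # first pass: per-atom facts
    raw = []
    for a in g.atoms:
        double_to: set[str] = set()
        double_to_aromatic = False
        for j in g.neighbors(a.index):
            b = g.bond_between(a.index, j)
            if b.order >= 2 and not b.aromatic:
                nbr = g.atom(j)
                double_to.add(nbr.element)
                if b.order == 2 and nbr.aromatic:
                    double_to_aromatic = True
        n_oxy = sum(1 for j in g.neighbors(a.index) if g.atom(j).element == "O")
        carboxyl_self = a.element == "C" and n_oxy >= 2 and "O" in double_to
        raw.append((double_to, double_to_aromatic, carboxyl_self))
    envs = []
    for a in g.atoms:
        double_to, double_to_aromatic, carboxyl_self = raw[a.index - 1]
        carboxyl_neighbor = any(
            g.atom(j).element == "C" and raw[j - 1][2] for j in g.neighbors(a.index)
        )
        envs.append(
            _AtomEnv(
                element=a.element,
                aromatic=a.aromatic,
                in_ring=ring_info.NumAtomRings(a.index - 1) > 0,
                h=a.implicit_h,
                heavy_degree=len(g.neighbors(a.index)),
                unsaturated=bool(double_to) and not a.aromatic,
                double_to=frozenset(double_to),
                double_to_aromatic=double_to_aromatic,
                carboxyl_self=carboxyl_self,
                carboxyl_neighbor=carboxyl_neighbor,
            )
        )
    return envs


def _rule_matches(rule: dict, env: _AtomEnv) -> bool:
    if env.element not in rule.get("elements", []):
        return False
    checks = (
        ("aromatic", lambda v: env.aromatic == v),
        ("in_ring", lambda v: env.in_ring == v),
        ("min_h", lambda v: env.h >= v),
        ("max_h", lambda v: env.h <= v),
        ("heavy_degree", lambda v: env.heavy_degree == v),
        ("min_heavy_degree", lambda v: env.heavy_degree >= v),
        ("max_heavy_degree", lambda v: env.heavy_degree <= v),
        ("unsaturated", lambda v: env.unsaturated == v),
        ("double_to", lambda v: bool(env.double_to & set(v))),
        ("double_to_aromatic", lambda v: env.double_to_aromatic == v),
        ("carboxyl_self", lambda v: env.carboxyl_self == v),
        ("carboxyl_neighbor", lambda v: env.carboxyl_neighbor == v),
    )
    for field_name, check in checks:
        if field_name in rule and not check(rule[field_name]):
            return False
    return True


def assign_types(g: MolecularGraph) -> list[TypedAtom]:
    """Assign one KEGG-style type code to every heavy atom.

    Typing is a pure function of the graph (element, charge, bonding,
    aromaticity); re-typing an unchanged graph yields identical results.
    """
    rules = load_type_table()
    out = []
    for a, env in zip(g.atoms, _environments(g)):
        code = f"{a.element}?"
        for rule in rules:
            if _rule_matches(rule, env):
                code = rule["code"]
                break
        out.append(TypedAtom(index=a.index, element=a.element, kegg_type=code))
    return out


def type_map(g: MolecularGraph) -> dict[int, str]:
    """Convenience: atom index -> KEGG type code."""
    return {t.index: t.kegg_type for t in assign_types(g)}
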