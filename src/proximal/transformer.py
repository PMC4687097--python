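"""Generating candidate metabolites by replaying look-up table rules.

Every heavy atom of the query is treated as a candidate reaction center and
keyed by its two-level neighbourhood.  Sites whose keys coincide are
symmetry-equivalent (e.g. the two rings of bisphenol A) and only one
representative per class is transformed, so symmetric sites do not generate
duplicate products.  Matching against a look-up table is exact on all three
key fields; a matched rule is then *embedded* - its reactant-side template
is mapped onto the query rooted at the site - and its edit script (atom
removals, bond rewrites, fragment grafts) is replayed.  The template
embedding acts as a finer filter than the key: a rule whose replay needs
context the query lacks (say, the ring nitrogen of an acylaminophenol)
simply does not embed and produces nothing.

Products are validated (valence via sanitisation), deduplicated by
canonical key, and can be chained: by default Phase II conjugations are
applied both to the query and to each Phase I product, mirroring the
two-layer Phase I -> Phase II pattern of hepatic xenobiotic metabolism.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field, replace

from .atom_typing import type_map
from .chem_io import Atom, Bond, MolecularGraph, ValenceError, canonical_key
from .table_builder import LookupKey, LookupTable, TransformationRule, extract_key

__all__ = [
    "ReactionCenterSite",
    "PredictedProduct",
    "ProductRejected",
    "enumerate_sites",
    "match_sites",
    "apply_rule",
    "replay_rule",
    "predict",
]

log = logging.getLogger(__name__)


class ProductRejected(ValueError):
    """A rule could not be applied at a site (no embedding, bad valence, ...)."""


@dataclass(frozen=True)
class ReactionCenterSite:
    atom_index: int
    key: LookupKey
    symmetry_class: int
    representative: bool


@dataclass(frozen=True)
class PredictedProduct:
    graph: MolecularGraph
    site: ReactionCenterSite
    rule: TransformationRule
    phase_chain: tuple[str, ...]
    enzymes: frozenset[str]
    canonical: str


def enumerate_sites(g: MolecularGraph, types: dict[int, str] | None = None) -> list[ReactionCenterSite]:
    """One candidate reaction-center site per heavy atom.

    Sites sharing an identical (center, adjacent, distant) key tuple form one
    symmetry class; the lowest-indexed member is the class representative.
    """
    if types is None:
        types = type_map(g)
    class_of: dict[LookupKey, int] = {}
    rep_seen: set[int] = set()
    sites = []
    for a in g.atoms:
        key = extract_key(g, types, a.index)
        cls = class_of.setdefault(key, len(class_of))
        rep = cls not in rep_seen
        rep_seen.add(cls)
        sites.append(ReactionCenterSite(a.index, key, cls, rep))
    return sites


def match_sites(
    sites: list[ReactionCenterSite], table: LookupTable
) -> list[tuple[ReactionCenterSite, TransformationRule]]:
    """Exact key matches for one representative per symmetry class."""
    out = []
    for site in sites:
        if not site.representative:
            continue
        for rule in table.lookup(site.key):
            out.append((site, rule))
    return out


# ---------------------------------------------------------------------------
# template embedding + edit replay
# ---------------------------------------------------------------------------


def _find_embedding(
    g: MolecularGraph, types: dict[int, str], center: int, rule: TransformationRule
) -> dict[int, int] | None:
    """Map template positions onto query atoms, rooted at *center*.

    Atoms must agree on element and KEGG type; template bonds must exist in
    the query with a compatible order (aromatic matches aromatic, otherwise
    exact Kekule order).  Returns the first embedding in deterministic
    (ascending-candidate) order, or None.
    """
    t_elem = {pos: el for pos, el, _ in rule.template_atoms}
    t_type = {pos: ty for pos, _, ty in rule.template_atoms}
    t_adj: dict[int, list[tuple[int, int, bool]]] = {pos: [] for pos in t_elem}
    for pi, pj, order, aromatic in rule.template_bonds:
        t_adj[pi].append((pj, order, aromatic))
        t_adj[pj].append((pi, order, aromatic))

    if g.atom(center).element != t_elem[0] or types[center] != t_type[0]:
        return None

    # BFS order over the (connected) template so each position has a matched parent
    bfs_order = []
    parent: dict[int, int] = {}
    seen = {0}
    dq = deque([0])
    while dq:
        cur = dq.popleft()
        bfs_order.append(cur)
        for nxt, _, _ in sorted(t_adj[cur]):
            if nxt not in seen:
                seen.add(nxt)
                parent[nxt] = cur
                dq.append(nxt)
    if len(bfs_order) != len(t_elem):  # disconnected template cannot be embedded
        return None

    def bond_ok(qa: int, qb: int, order: int, aromatic: bool) -> bool:
        b = g.bond_between(qa, qb)
        if b is None:
            return False
        if aromatic:
            return b.aromatic
        return (not b.aromatic) and b.order == order

    assignment: dict[int, int] = {0: center}
    used = {center}

    def backtrack(k: int) -> bool:
        if k == len(bfs_order):
            return True
        pos = bfs_order[k]
        par = parent[pos]
        for cand in g.neighbors(assignment[par]):
            if cand in used:
                continue
            if g.atom(cand).element != t_elem[pos] or types[cand] != t_type[pos]:
                continue
            ok = True
            for other, order, aromatic in t_adj[pos]:
                if other in assignment and not bond_ok(cand, assignment[other], order, aromatic):
                    ok = False
                    break
            if not ok:
                continue
            assignment[pos] = cand
            used.add(cand)
            if backtrack(k + 1):
                return True
            del assignment[pos]
            used.discard(cand)
        return False

    return dict(assignment) if backtrack(1) else None


def replay_rule(g: MolecularGraph, center: int, rule: TransformationRule) -> MolecularGraph:
    """Apply *rule* to *g* at *center* and return the edited, re-sanitised graph.

    Raises :class:`ProductRejected` if the template does not embed, an edit
    would leave a dangling substituent, or the grafted structure violates
    standard valences.
    """
    types = type_map(g)
    emb = _find_embedding(g, types, center, rule)
    if emb is None:
        raise ProductRejected(f"rule template does not embed at atom {center}")
    matched = set(emb.values())
    removed = {emb[pos] for pos in rule.removed_positions}
    for ra in removed:
        for n in g.neighbors(ra):
            if n not in matched and n not in removed:
                raise ProductRejected(
                    f"removing atom {ra} would orphan unmatched substituent at atom {n}"
                )

    change_map: dict[tuple[int, int], int] = {}
    for pi, pj, new_order in rule.bond_changes:
        qa, qb = emb[pi], emb[pj]
        change_map[(min(qa, qb), max(qa, qb))] = new_order

    keep = [a for a in g.atoms if a.index not in removed]
    new_index = {a.index: k + 1 for k, a in enumerate(keep)}
    atoms = [
        Atom(index=new_index[a.index], element=a.element, formal_charge=a.formal_charge)
        for a in keep
    ]
    bonds: list[Bond] = []
    for b in g.bonds:
        if b.i in removed or b.j in removed:
            continue
        bk = b.key()
        if bk in change_map:
            new_order = change_map[bk]
            if new_order == 0:
                continue
            bonds.append(Bond(new_index[b.i], new_index[b.j], new_order))
        else:
            bonds.append(Bond(new_index[b.i], new_index[b.j], b.order, b.aromatic))

    # new atoms are appended after the original atoms (mol-file convention)
    frag_index = {}
    for fid, element, charge in rule.added_atoms:
        idx = len(atoms) + 1
        frag_index[fid] = idx
        atoms.append(Atom(index=idx, element=element, formal_charge=charge))
    for fi, fj, order in rule.added_bonds:
        bonds.append(Bond(frag_index[fi], frag_index[fj], order))
    for pos, fid, order in rule.attachments:
        bonds.append(Bond(new_index[emb[pos]], frag_index[fid], order))

    draft = MolecularGraph(atoms, bonds, name=g.name, source_id=g.source_id)
    try:
        mol = draft.to_rdkit(sanitize=True)
    except ValenceError as exc:
        raise ProductRejected(f"edited structure is not a valid molecule: {exc}") from exc
    return MolecularGraph.from_rdkit(mol, name=g.name, source_id=g.source_id)


def apply_rule(
    g: MolecularGraph,
    site: ReactionCenterSite,
    rule: TransformationRule,
    phase_chain: tuple[str, ...] | None = None,
) -> PredictedProduct:
    """Apply a matched rule at a site, yielding a PredictedProduct."""
    product = replay_rule(g, site.atom_index, rule)
    ck = canonical_key(product)
    if ck == canonical_key(g):
        raise ProductRejected("product is identical to the query")
    product = replace(
        product, name=f"{g.name or 'query'}|{'+'.join(phase_chain or (rule.phase,))}@{site.atom_index}"
    )
    return PredictedProduct(
        graph=product,
        site=site,
        rule=rule,
        phase_chain=tuple(phase_chain or (rule.phase,)),
        enzymes=rule.enzymes,
        canonical=ck,
    )


# ---------------------------------------------------------------------------
# end-to-end prediction
# ---------------------------------------------------------------------------


def _run_phase(
    mol: MolecularGraph, table: LookupTable, chain: tuple[str, ...]
) -> list[PredictedProduct]:
    out = []
    for site, rule in match_sites(enumerate_sites(mol), table):
        try:
            out.append(apply_rule(mol, site, rule, chain))
        except ProductRejected as exc:
            log.debug("site %d: %s", site.atom_index, exc)
    return out


def predict(
    g: MolecularGraph,
    phase_i: LookupTable,
    phase_ii: LookupTable,
    phases: frozenset[str] | set[str] = frozenset({"I", "II"}),
    depth: int = 2,
    reapply_phase_i: bool = False,
) -> list[PredictedProduct]:
    """Predict metabolites of *g* from Phase I / Phase II look-up tables.

    Default chaining (depth=2) is Phase I on the query, Phase II on the
    query, and Phase II on each Phase I product.  ``reapply_phase_i=True``
    additionally re-applies Phase I to Phase I products up to *depth*.
    Products are deduplicated by canonical key; enzyme sets are merged
    across duplicate generation paths.  Output order is stable: by chain
    length, chain, site atom, then canonical key.
    """
    query_ck = canonical_key(g)
    level_i: list[PredictedProduct] = []
    collected: list[PredictedProduct] = []

    if "I" in phases and depth >= 1:
        level_i = _run_phase(g, phase_i, ("I",))
        collected.extend(level_i)
        if reapply_phase_i:
            frontier = level_i
            chain_len = 2
            while chain_len <= depth and frontier:
                nxt = []
                for pp in frontier:
                    nxt.extend(_run_phase(pp.graph, phase_i, pp.phase_chain + ("I",)))
                collected.extend(nxt)
                frontier = nxt
                chain_len += 1
    if "II" in phases and depth >= 1:
        collected.extend(_run_phase(g, phase_ii, ("II",)))
        if depth >= 2:
            for pp in [p for p in collected if set(p.phase_chain) == {"I"}]:
                collected.extend(_run_phase(pp.graph, phase_ii, pp.phase_chain + ("II",)))

    collected.sort(
        key=lambda p: (len(p.phase_chain), p.phase_chain, p.site.atom_index, p.canonical)
    )
    unique: dict[str, PredictedProduct] = {}
    for pp in collected:
        if pp.canonical == query_ck:
            continue
        if pp.canonical in unique:
            prev = unique[pp.canonical]
            unique[pp.canonical] = replace(prev, enzymes=prev.enzymes | pp.enzymes)
        else:
            unique[pp.canonical] = pp
    return list(unique.values())
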