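"""Reactant-product atom alignment by maximum common subgraph search.

Aligning the two sides of a reaction is what localises the chemistry: the
atoms inside the common subgraph are unchanged scaffold, everything else is
the transformation.  The search finds a maximum *connected* common induced
subgraph between two element-labelled molecular graphs:

* atoms may align only if their elements match (types may differ - a type
  change at an aligned pair is precisely what marks a reaction center);
* bond *presence* must agree on both sides (orders may differ, since
  oxidation-state changes at the center would otherwise break alignment);
* the aligned subgraph must be connected.

The search builds the modular product of the two graphs and runs a
branch-and-bound maximum c-clique search (cliques whose "both-bonded" edges
span a connected subgraph).  Among equal-size maxima the lexicographically
smallest pair list by (reactant_index, product_index) is returned, so the
alignment is deterministic.  A configurable node budget degrades the search
gracefully to best-found-so-far on large inputs.

``brute_force_mcs`` is an independent oracle for small molecules: it
enumerates connected induced subgraphs of the reactant directly and tests
embeddability into the product with VF2 (networkx).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .chem_io import MolecularGraph

__all__ = ["AtomAlignment", "max_common_subgraph", "brute_force_mcs", "alignment_tsv"]

DEFAULT_NODE_BUDGET = 2_000_000


@dataclass(frozen=True)
class AtomAlignment:
    """Injective reactant<->product atom correspondence."""

    pairs: tuple[tuple[int, int], ...]  # sorted by reactant index
    score: int

    def reactant_to_product(self) -> dict[int, int]:
        return dict(self.pairs)

    def product_to_reactant(self) -> dict[int, int]:
        return {p: r for r, p in self.pairs}


def _adjacency(g: MolecularGraph) -> dict[int, set[int]]:
    return {a.index: set(g.neighbors(a.index)) for a in g.atoms}


def max_common_subgraph(
    r: MolecularGraph,
    p: MolecularGraph,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> AtomAlignment:
    """Maximum connected common induced subgraph alignment of *r* and *p*."""
    if r.n_atoms == 0 or p.n_atoms == 0:
        raise ValueError("both molecules must be non-empty")
    radj = _adjacency(r)
    padj = _adjacency(p)
    vertices = [
        (ra.index, pa.index)
        for ra in r.atoms
        for pa in p.atoms
        if ra.element == pa.element
    ]
    nv = len(vertices)
    if nv == 0:
        return AtomAlignment(pairs=(), score=0)
    vidx = {v: k for k, v in enumerate(vertices)}

    comp: list[set[int]] = [set() for _ in range(nv)]  # compatible (c or d edge)
    cadj: list[set[int]] = [set() for _ in range(nv)]  # both-bonded (c edge)
    for k1, (r1, p1) in enumerate(vertices):
        for k2 in range(k1 + 1, nv):
            r2, p2 = vertices[k2]
            if r1 == r2 or p1 == p2:
                continue
            rb = r2 in radj[r1]
            pb = p2 in padj[p1]
            if rb != pb:
                continue
            comp[k1].add(k2)
            comp[k2].add(k1)
            if rb:
                cadj[k1].add(k2)
                cadj[k2].add(k1)

    best_pairs: list[tuple[int, int]] = []
    nodes_left = [node_budget]

    def record(clique: list[int]) -> None:
        pairs = sorted(vertices[k] for k in clique)
        nonlocal best_pairs
        if len(pairs) > len(best_pairs) or (len(pairs) == len(best_pairs) and pairs < best_pairs):
            best_pairs = pairs

    class _Budget(Exception):
        pass

    def expand(clique: list[int], cand: set[int], pool: set[int]) -> None:
        # cand: compatible with the clique and c-adjacent to it (may extend)
        # pool: compatible but not yet c-connected (may join once connected)
        nodes_left[0] -= 1
        if nodes_left[0] < 0:
            raise _Budget
        record(clique)
        for u in sorted(cand):
            if len(clique) + len(cand) + len(pool) < len(best_pairs):
                return
            cand.discard(u)
            new_cand = (cand & comp[u]) | (pool & cadj[u])
            new_pool = (pool & comp[u]) - cadj[u]
            expand(clique + [u], new_cand, new_pool)

    try:
        banned: set[int] = set()
        for k in range(nv):
            allowed_comp = comp[k] - banned
            expand([k], cadj[k] - banned, allowed_comp - cadj[k])
            banned.add(k)
    except _Budget:
        pass  # heuristic mode: return best found within budget

    return AtomAlignment(pairs=tuple(best_pairs), score=len(best_pairs))


_BRUTE_FORCE_LIMIT = 12


def _to_nx(g: MolecularGraph) -> nx.Graph:
    G = nx.Graph()
    for a in g.atoms:
        G.add_node(a.index, element=a.element)
    for b in g.bonds:
        G.add_edge(b.i, b.j)
    return G


def _connected_subsets(G: nx.Graph, size: int) -> list[frozenset[int]]:
    """All connected node subsets of exactly *size* nodes (bitmask sweep)."""
    nodes = sorted(G.nodes)
    results = []
    for mask in range(1, 1 << len(nodes)):
        if bin(mask).count("1") != size:
            continue
        subset = {nodes[i] for i in range(len(nodes)) if mask >> i & 1}
        if nx.is_connected(G.subgraph(subset)):
            results.append(frozenset(subset))
    return sorted(results, key=sorted)


def brute_force_mcs(r: MolecularGraph, p: MolecularGraph) -> AtomAlignment:
    """Exact maximum connected common induced subgraph by exhaustive search.

    Test oracle, independent of the clique-based search: enumerates connected
    induced reactant subgraphs by decreasing size and checks each for an
    element-preserving induced embedding into the product via VF2.
    Refuses molecules above 12 heavy atoms.
    """
    if r.n_atoms > _BRUTE_FORCE_LIMIT or p.n_atoms > _BRUTE_FORCE_LIMIT:
        raise ValueError(f"brute_force_mcs is limited to {_BRUTE_FORCE_LIMIT} heavy atoms")
    if r.n_atoms == 0 or p.n_atoms == 0:
        raise ValueError("both molecules must be non-empty")
    rG = _to_nx(r)
    pG = _to_nx(p)
    node_match = nx.algorithms.isomorphism.categorical_node_match("element", None)
    for size in range(min(r.n_atoms, p.n_atoms), 0, -1):
        best: list[tuple[int, int]] | None = None
        for subset in _connected_subsets(rG, size):
            sub = rG.subgraph(subset)
            gm = nx.algorithms.isomorphism.GraphMatcher(pG, sub, node_match=node_match)
            for mapping in gm.subgraph_isomorphisms_iter():  # induced embeddings
                pairs = sorted((rn, pn) for pn, rn in mapping.items())
                if best is None or pairs < best:
                    best = pairs
        if best is not None:
            return AtomAlignment(pairs=tuple(best), score=size)
    return AtomAlignment(pairs=(), score=0)


def alignment_tsv(a: AtomAlignment, r_types: dict[int, str], p_types: dict[int, str]) -> str:
    """Tab-separated alignment dump: reactant index/type, product index/type."""
    lines = ["reactant_index\treactant_type\tproduct_index\tproduct_type"]
    for ri, pi in a.pairs:
        lines.append(f"{ri}\t{r_types[ri]}\t{pi}\t{p_types[pi]}")
    return "\n".join(lines) + "\n"
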