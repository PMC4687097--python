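"""Molecular structure I/O and the molecular-graph data model.

Molecules are stored as heavy-atom graphs with mol-file semantics: atoms are
numbered 1..N in file order, hydrogens are implicit, bond orders are Kekule
(1|2|3) with a separate aromaticity flag.  RDKit is used behind the scenes
for parsing, writing, valence/implicit-H bookkeeping and canonical identity;
the graph model itself is independent so that downstream modules can edit
structures freely before re-validating them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "MolfileError",
    "ValenceError",
    "read_molfile",
    "write_molfile",
    "from_smiles",
    "canonical_key",
]


class MolfileError(ValueError):
    """Raised when a molfile cannot be parsed."""


class ValenceError(ValueError):
    """Raised when a graph cannot be realised as a valid molecule."""


@dataclass(frozen=True)
class Atom:
    index: int  # 1-based position, mol-file convention
    element: str
    formal_charge: int = 0
    implicit_h: int = 0
    aromatic: bool = False


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: int = 1  # Kekule order 1|2|3
    aromatic: bool = False

    def key(self) -> tuple[int, int]:
        return (self.i, self.j) if self.i < self.j else (self.j, self.i)


@dataclass
class MolecularGraph:
    """Simple undirected heavy-atom graph of a compound."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for pos, a in enumerate(self.atoms, start=1):
            if a.index != pos:
                raise ValueError(f"atom indices must be contiguous 1..N; got {a.index} at position {pos}")
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError(f"self-bond on atom {b.i}")
            if not (1 <= b.i <= n and 1 <= b.j <= n):
                raise ValueError(f"bond ({b.i},{b.j}) references a missing atom")
            if b.key() in seen:
                raise ValueError(f"duplicate bond ({b.i},{b.j})")
            seen.add(b.key())
        self._adj: dict[int, list[int]] | None = None
        self._bond_map: dict[tuple[int, int], Bond] | None = None

    # -- graph accessors -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom(self, index: int) -> Atom:
        return self.atoms[index - 1]

    def neighbors(self, index: int) -> list[int]:
        if self._adj is None:
            adj: dict[int, list[int]] = {a.index: [] for a in self.atoms}
            for b in self.bonds:
                adj[b.i].append(b.j)
                adj[b.j].append(b.i)
            self._adj = {k: sorted(v) for k, v in adj.items()}
        return self._adj[index]

    def bond_between(self, i: int, j: int) -> Bond | None:
        if self._bond_map is None:
            self._bond_map = {b.key(): b for b in self.bonds}
        return self._bond_map.get((i, j) if i < j else (j, i))

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(list(self.atoms), list(self.bonds), self.name, self.source_id)

    # -- RDKit bridge ----------------------------------------------------

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        """Realise the graph as an RDKit molecule.

        Raises ValenceError if the Kekule bond orders are inconsistent with
        standard valences (used by the transformer to reject bad grafts).
        """
        rw = Chem.RWMol()
        for a in self.atoms:
            at = Chem.Atom(a.element)
            at.SetFormalCharge(a.formal_charge)
            at.SetNoImplicit(False)
            rw.AddAtom(at)
        order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
        for b in self.bonds:
            rw.AddBond(b.i - 1, b.j - 1, order_map[b.order])
        mol = rw.GetMol()
        if sanitize:
            try:
                Chem.SanitizeMol(mol)
            except Exception as exc:  # rdkit raises several exception types
                raise ValenceError(f"graph is not a valid molecule: {exc}") from exc
        return mol

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, name: str = "", source_id: str = "") -> "MolecularGraph":
        """Build a graph from a sanitized RDKit molecule (heavy atoms only)."""
        mol = Chem.RemoveHs(mol)
        km = Chem.Mol(mol)
        Chem.Kekulize(km, clearAromaticFlags=False)
        atoms = [
            Atom(
                index=a.GetIdx() + 1,
                element=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                implicit_h=a.GetTotalNumHs(),
                aromatic=a.GetIsAromatic(),
            )
            for a in km.GetAtoms()
        ]
        bonds = [
            Bond(
                i=b.GetBeginAtomIdx() + 1,
                j=b.GetEndAtomIdx() + 1,
                order=int(b.GetBondTypeAsDouble()),
                aromatic=b.GetIsAromatic(),
            )
            for b in km.GetBonds()
        ]
        return cls(atoms, bonds, name=name, source_id=source_id)


_ALLOWED_COUNT = 999


def _parse_counts_line(line: str, lineno: int) -> tuple[int, int]:
    if "V3000" in line:
        raise MolfileError(f"line {lineno}: V3000 molfiles are not supported (V2000 only)")
    try:
        natoms = int(line[0:3])
        nbonds = int(line[3:6])
    except (ValueError, IndexError) as exc:
        raise MolfileError(f"line {lineno}: malformed counts line {line!r}") from exc
    if not (0 <= natoms <= _ALLOWED_COUNT and 0 <= nbonds <= _ALLOWED_COUNT):
        raise MolfileError(f"line {lineno}: implausible atom/bond counts in {line!r}")
    return natoms, nbonds


def read_molfile(text: str, name: str = "", source_id: str = "") -> MolecularGraph:
    """Parse an MDL molfile (V2000) into a MolecularGraph.

    Explicit hydrogens in the input are folded into implicit-H counts; the
    heavy-atom order of the file is preserved.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("molfile has fewer than 4 lines (no counts line)")
    natoms, nbonds = _parse_counts_line(lines[3], 4)
    if natoms == 0:
        raise MolfileError("line 4: molfile declares zero atoms")
    block_len = 4 + natoms + nbonds
    if len(lines) < block_len:
        raise MolfileError(
            f"molfile truncated: counts line declares {natoms} atoms / {nbonds} bonds "
            f"but only {len(lines)} lines are present"
        )
    ptable = Chem.GetPeriodicTable()
    for k in range(natoms):
        lineno = 5 + k
        line = lines[4 + k]
        if len(line) < 34:
            raise MolfileError(f"line {lineno}: atom line too short: {line!r}")
        symbol = line[31:34].strip()
        try:
            if ptable.GetAtomicNumber(symbol) == 0:
                raise ValueError
        except Exception as exc:
            raise MolfileError(f"line {lineno}: unknown element symbol {symbol!r}") from exc
    mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
    if mol is None:
        raise MolfileError("RDKit could not parse/sanitize the molfile")
    if not name:
        name = lines[0].strip()
    return MolecularGraph.from_rdkit(mol, name=name, source_id=source_id)


def write_molfile(g: MolecularGraph) -> str:
    """Emit a V2000 molblock, preserving atom order."""
    if g.n_atoms == 0:
        raise ValueError("cannot write an empty molecule")
    mol = g.to_rdkit(sanitize=True)
    mol.SetProp("_Name", g.name or "")
    return Chem.MolToMolBlock(mol, kekulize=True)


def from_smiles(smiles: str, name: str = "", source_id: str = "") -> MolecularGraph:
    """Convenience SMILES reader.

    Atom order is the SMILES parser's traversal order and is NOT canonical;
    fixtures that rely on specific atom numbering ship as molfiles instead.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return MolecularGraph.from_rdkit(mol, name=name, source_id=source_id)


def canonical_key(g: MolecularGraph) -> str:
    """Canonical text identity: equal for isomorphic graphs.

    Uses the canonical SMILES of the (stereo-free) heavy-atom graph, which is
    invariant under atom renumbering and Kekule-structure choice.
    """
    return Chem.MolToSmiles(g.to_rdkit(sanitize=True))
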