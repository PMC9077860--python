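"""Molecular graph I/O.

Molecules are represented as explicit-hydrogen, Kekulized labeled graphs
(:class:`Molecule`), thin and immutable enough for descriptor work while
round-tripping through RDKit for parsing, sanitization and serialization.
Stereochemistry is parsed but discarded: all downstream descriptors are
2D/topological and therefore stereo-blind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# Valence-electron counts and periods for the neutral main-group elements the
# pipeline supports.  Zv is taken from the neutral element even for charged
# input (the descriptor scheme operates on neutral organics).
_VALENCE_ELECTRONS = {
    "H": 1, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7,
    "Si": 4, "P": 5, "S": 6, "Cl": 7, "Br": 7, "I": 7,
}
_PERIOD = {
    "H": 1,
    "B": 2, "C": 2, "N": 2, "O": 2, "F": 2,
    "Si": 3, "P": 3, "S": 3, "Cl": 3,
    "Br": 4, "I": 5,
}


class MoleculeError(ValueError):
    """Raised for unparsable or chemically inconsistent structure input."""


@dataclass(frozen=True)
class Atom:
    """A node of the molecular graph.

    Attributes
    ----------
    index : int
        0-based position in the parent molecule's atom list.
    element : str
        Element symbol.
    Z : int
        Atomic number.
    Zv : int
        Valence electron count of the neutral element.
    PN : int
        Period number.
    is_hydrogen : bool
    formal_charge : int
        Carried through from input; expected 0 for this chemistry.
    """

    index: int
    element: str
    Z: int
    Zv: int
    PN: int
    is_hydrogen: bool
    formal_charge: int = 0

    def __post_init__(self) -> None:
        if self.Z < 1 or not (1 <= self.Zv <= 8) or self.PN < 1:
            raise MoleculeError(
                f"inconsistent atom {self.element}: Z={self.Z} Zv={self.Zv} PN={self.PN}"
            )
        if self.is_hydrogen and (self.Z != 1 or self.Zv != 1 or self.PN != 1):
            raise MoleculeError("hydrogen must have Z = Zv = PN = 1")


@dataclass(frozen=True)
class Bond:
    """An edge of the molecular graph with a definite (Kekulized) order."""

    i: int
    j: int
    order: int
    aromatic: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise MoleculeError("bond endpoints must be distinct")
        if self.order not in (1, 2, 3):
            raise MoleculeError(f"bond order {self.order} outside 1-3")


@dataclass
class Molecule:
    """Explicit-hydrogen, Kekulized molecular graph.

    The hydrogen-suppressed view (heavy atoms only) must be connected;
    every hydrogen carries exactly one bond.
    """

    id: str
    atoms: list[Atom]
    bonds: list[Bond]
    name: str | None = None
    _adj: dict[int, list[tuple[int, Bond]]] = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self._adj = {a.index: [] for a in self.atoms}
        for b in self.bonds:
            self._adj[b.i].append((b.j, b))
            self._adj[b.j].append((b.i, b))
        for a in self.atoms:
            if a.is_hydrogen and len(self._adj[a.index]) != 1:
                raise MoleculeError(f"{self.id}: hydrogen {a.index} has {len(self._adj[a.index])} bonds")
        if self.heavy_atoms() and not self._heavy_connected():
            raise MoleculeError(f"{self.id}: hydrogen-suppressed graph is disconnected")

    # -- graph views ---------------------------------------------------------

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_bonds(self) -> list[Bond]:
        h = {a.index for a in self.atoms if a.is_hydrogen}
        return [b for b in self.bonds if b.i not in h and b.j not in h]

    def neighbors(self, idx: int) -> list[tuple[int, Bond]]:
        return list(self._adj[idx])

    def heavy_neighbors(self, idx: int) -> list[tuple[Atom, Bond]]:
        return [
            (self.atoms[n], b) for n, b in self._adj[idx] if not self.atoms[n].is_hydrogen
        ]

    def heavy_graph(self) -> nx.Graph:
        """Hydrogen-suppressed graph as networkx, for distance queries."""
        g = nx.Graph()
        g.add_nodes_from(a.index for a in self.heavy_atoms())
        g.add_edges_from((b.i, b.j) for b in self.heavy_bonds())
        return g

    def n_heavy(self) -> int:
        return sum(1 for a in self.atoms if not a.is_hydrogen)

    def n_atoms(self) -> int:
        return len(self.atoms)

    def _heavy_connected(self) -> bool:
        heavy = {a.index for a in self.heavy_atoms()}
        start = next(iter(heavy))
        seen = {start}
        stack = [start]
        while stack:
            for n, _ in self._adj[stack.pop()]:
                if n in heavy and n not in seen:
                    seen.add(n)
                    stack.append(n)
        return seen == heavy


# ---------------------------------------------------------------------------
# RDKit conversion
# ---------------------------------------------------------------------------

def _element_info(symbol: str) -> tuple[int, int]:
    if symbol not in _VALENCE_ELECTRONS:
        raise MoleculeError(f"unsupported element {symbol!r}")
    return _VALENCE_ELECTRONS[symbol], _PERIOD[symbol]


def from_rdkit(rdmol: Chem.Mol, mol_id: str, name: str | None = None) -> Molecule:
    """Convert an RDKit mol to a :class:`Molecule`.

    Hydrogens are made explicit and aromatic rings Kekulized; the aromatic
    flag of each ring bond is preserved alongside its Kekulé order.
    """
    rdmol = Chem.AddHs(rdmol)
    aromatic_pairs = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in rdmol.GetBonds()
        if b.GetIsAromatic()
    }
    Chem.Kekulize(rdmol, clearAromaticFlags=True)
    atoms = []
    for a in rdmol.GetAtoms():
        sym = a.GetSymbol()
        zv, pn = _element_info(sym)
        atoms.append(
            Atom(
                index=a.GetIdx(),
                element=sym,
                Z=a.GetAtomicNum(),
                Zv=zv,
                PN=pn,
                is_hydrogen=sym == "H",
                formal_charge=a.GetFormalCharge(),
            )
        )
    bonds = []
    for b in rdmol.GetBonds():
        order = int(b.GetBondTypeAsDouble())
        if order not in (1, 2, 3):
            raise MoleculeError(f"{mol_id}: unsupported bond type {b.GetBondType()}")
        pair = frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        bonds.append(
            Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, aromatic=pair in aromatic_pairs)
        )
    return Molecule(id=mol_id, atoms=atoms, bonds=bonds, name=name)


def to_rdkit(mol: Molecule) -> Chem.Mol:
    """Rebuild an RDKit mol (explicit H) from a :class:`Molecule`."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        ra = Chem.Atom(a.Z)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNoImplicit(True)
        rw.AddAtom(ra)
    order_map = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, order_map[b.order])
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def canonical_smiles(mol: Molecule) -> str:
    return Chem.MolToSmiles(Chem.RemoveHs(to_rdkit(mol)))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_smiles(path: str | Path, has_header: bool = False) -> list[Molecule]:
    """Read a ``.smi`` file: one ``SMILES<whitespace>ID`` pair per line."""
    mols: list[Molecule] = []
    seen_ids: set[str] = set()
    lines = Path(path).read_text().splitlines()
    if has_header:
        lines = lines[1:]
    for lineno, line in enumerate(lines, start=2 if has_header else 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        mol_id = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
        rdmol = Chem.MolFromSmiles(smiles)
        if rdmol is None:
            raise MoleculeError(f"line {lineno}: unparsable SMILES for id {mol_id!r}")
        if mol_id in seen_ids:
            raise MoleculeError(f"line {lineno}: duplicate id {mol_id!r}")
        seen_ids.add(mol_id)
        mols.append(from_rdkit(rdmol, mol_id))
    return mols


def write_smiles(mols: Iterable[Molecule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{canonical_smiles(m)}\t{m.id}\n")


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read an SDF (V2000) file; explicit hydrogens are added if absent."""
    mols: list[Molecule] = []
    seen_ids: set[str] = set()
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for rec, rdmol in enumerate(supplier):
        if rdmol is None:
            raise MoleculeError(f"SDF record {rec}: malformed connection table")
        mol_id = rdmol.GetProp("_Name").strip() if rdmol.HasProp("_Name") else ""
        if not mol_id:
            mol_id = f"mol{rec}"
        if mol_id in seen_ids:
            raise MoleculeError(f"SDF record {rec}: duplicate id {mol_id!r}")
        seen_ids.add(mol_id)
        mols.append(from_rdkit(rdmol, mol_id))
    return mols


def write_sdf(mols: Iterable[Molecule], path: str | Path) -> None:
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    for m in mols:
        rd = to_rdkit(m)
        rd.SetProp("_Name", m.id)
        writer.write(rd)
    writer.close()


def read_activity(path: str | Path, value_kind: str = "pLC50") -> dict[str, float]:
    """Read an activity CSV (columns ``id,value``) into an id -> pLC50 map.

    ``value_kind='LC50'`` converts on the fly as pLC50 = -log10(LC50) in the
    source's concentration units; ``'pLC50'`` passes values through.
    """
    if value_kind not in ("LC50", "pLC50"):
        raise ValueError(f"value_kind must be 'LC50' or 'pLC50', got {value_kind!r}")
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "id" not in cols or "value" not in cols:
        raise ValueError(f"activity CSV must have columns id,value; got {list(df.columns)}")
    ids = df[cols["id"]].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].tolist()
        raise ValueError(f"duplicate compound ids in activity file: {dupes}")
    out: dict[str, float] = {}
    for mol_id, val in zip(ids, df[cols["value"]].astype(float)):
        if value_kind == "LC50":
            if val <= 0:
                raise ValueError(f"non-positive LC50 for id {mol_id!r}: {val}")
            out[mol_id] = -math.log10(val)
        else:
            out[mol_id] = val
    return out


def total_hydrogens(mol: Molecule) -> int:
    return sum(1 for a in mol.atoms if a.is_hydrogen)


def heavy_bond_order_sum(mol: Molecule, idx: int) -> int:
    return sum(b.order for _, b in mol.neighbors(idx))
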