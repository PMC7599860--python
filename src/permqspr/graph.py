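"""Heavy-atom molecular graphs.

The graph is the substrate for every topological descriptor in this
package: hydrogens are implicit (stored as a per-atom count), bonds carry
an order (1, 2, 3 or ``"ar"`` for aromatic) and a ring-membership flag.
Structures can come from SMILES (parsed with RDKit behind a thin adapter)
or from an explicit JSON-style mapping, so that graph-only workflows never
touch a chemistry dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

AROMATIC = "ar"

#: Elements accepted for organic small molecules.
ORGANIC_ELEMENTS = {"C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si"}

ATOMIC_MASS = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "Br": 79.904, "I": 126.904,
}

ATOMIC_NUMBER = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Br": 35, "I": 53,
}

#: Valence (outer-shell) electron counts used for the valence delta.
VALENCE_ELECTRONS = {
    "B": 3, "C": 4, "N": 5, "O": 6, "F": 7, "Si": 4, "P": 5, "S": 6,
    "Cl": 7, "Br": 7, "I": 7,
}


class StructureParseError(ValueError):
    """Raised when a SMILES string or graph mapping cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    element: str
    n_h: int  # implicit hydrogen count

    def __post_init__(self) -> None:
        if self.element not in ORGANIC_ELEMENTS:
            raise StructureParseError(f"unsupported element {self.element!r}")
        if self.n_h < 0:
            raise StructureParseError("negative implicit-H count")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: Any  # 1 | 2 | 3 | "ar"
    in_ring: bool = False

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise StructureParseError(f"self-loop on atom {self.i}")
        if self.order not in (1, 2, 3, AROMATIC):
            raise StructureParseError(f"bad bond order {self.order!r}")


@dataclass
class MolecularGraph:
    """Connected heavy-atom graph of a single molecule."""

    atoms: list[Atom]
    bonds: list[Bond]
    label: str | None = None
    _adj: list[list[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise StructureParseError("empty molecule")
        seen: set[tuple[int, int]] = set()
        adj: list[list[int]] = [[] for _ in range(n)]
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise StructureParseError(f"bond index out of range: {b.i}-{b.j}")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise StructureParseError(f"duplicate bond {key}")
            seen.add(key)
            adj[b.i].append(b.j)
            adj[b.j].append(b.i)
        self._adj = adj
        if n > 1 and not self._connected():
            raise StructureParseError("graph is disconnected (multi-fragment input)")

    def _connected(self) -> bool:
        stack, seen = [0], {0}
        while stack:
            for nb in self._adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self.atoms)

    # ---- elementary invariants -------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self, i: int) -> int:
        return len(self._adj[i])

    def degrees(self) -> list[int]:
        return [len(a) for a in self._adj]

    def neighbors(self, i: int) -> list[int]:
        return list(self._adj[i])

    @property
    def cyclomatic_number(self) -> int:
        return self.n_bonds - self.n_atoms + 1

    def bond_between(self, i: int, j: int) -> Bond | None:
        for b in self.bonds:
            if {b.i, b.j} == {i, j}:
                return b
        return None

    # ---- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "atoms": [[a.element, a.n_h] for a in self.atoms],
            "bonds": [[b.i, b.j, b.order, b.in_ring] for b in self.bonds],
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "MolecularGraph":
        try:
            atoms = [Atom(str(e), int(h)) for e, h in d["atoms"]]
            bonds = []
            for rec in d["bonds"]:
                i, j, o = rec[0], rec[1], rec[2]
                ring = bool(rec[3]) if len(rec) > 3 else False
                bonds.append(Bond(int(i), int(j), o if o == AROMATIC else int(o), ring))
        except (KeyError, TypeError, ValueError, IndexError) as exc:
            raise StructureParseError(f"malformed graph mapping: {exc}") from exc
        return cls(atoms=atoms, bonds=bonds, label=d.get("label"))


def parse_structure(smiles: str, label: str | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    RDKit performs the chemistry (valence, aromaticity, ring perception);
    only the heavy-atom connectivity, implicit-H counts, bond orders and
    ring flags are retained.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise StructureParseError(f"unparsable SMILES: {smiles!r}")
    atoms = []
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        if sym not in ORGANIC_ELEMENTS:
            raise StructureParseError(
                f"unsupported element {sym!r} in {smiles!r}"
            )
        atoms.append(Atom(sym, a.GetTotalNumHs()))
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: AROMATIC,
    }
    bonds = []
    for b in mol.GetBonds():
        try:
            order = order_map[b.GetBondType()]
        except KeyError:
            raise StructureParseError(
                f"unsupported bond type {b.GetBondType()} in {smiles!r}"
            ) from None
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, b.IsInRing()))
    return MolecularGraph(atoms=atoms, bonds=bonds, label=label)


def read_smiles_file(lines: Iterable[str]) -> list[MolecularGraph]:
    """Read a .smi file: one ``SMILES [identifier]`` record per line."""
    out = []
    for ln, raw in enumerate(lines, 1):
        txt = raw.strip()
        if not txt or txt.startswith("#"):
            continue
        parts = txt.split(None, 1)
        smiles = parts[0]
        label = parts[1].strip() if len(parts) > 1 else f"mol{ln}"
        out.append(parse_structure(smiles, label=label))
    return out
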