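"""Graph-topological and count descriptors.

Implements the connectivity (chi), Kier shape (kappa), Balaban J and
simple count descriptors used throughout the pipeline.  All indices are
computed on the heavy-atom graph with hydrogens implicit; aromatic bonds
count as order 1 for rotatability and are always ring bonds.

Conventions (documented, oracle-tested):

* ``chi0_C``/``chi1_C`` restrict the sums to carbon atoms / C-C bonds but
  keep the *full-graph* degrees (the common descriptor-software choice).
* Kier kappas are the plain (non-alpha-corrected) indices by default; the
  alpha-modified variants are available via ``alpha=True``.
* Indices undefined for a molecule size (kappa2 below 3 atoms, kappa3
  below 4, or a zero path count) come back as ``None`` — never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graph import (
    AROMATIC,
    ATOMIC_MASS,
    ATOMIC_NUMBER,
    VALENCE_ELECTRONS,
    MolecularGraph,
)

__all__ = [
    "DescriptorVector",
    "DESCRIPTOR_COLUMNS",
    "chi_indices",
    "kier_indices",
    "count_descriptors",
    "balaban_j",
    "compute_descriptors",
    "descriptor_table",
    "path_count",
]


@dataclass
class DescriptorVector:
    """One molecule's descriptor values, in the fixed export order."""

    weight: float
    a_nH: int
    a_nC: int
    a_nO: int
    b_count: int
    b_single: int
    b_double: int
    b_rotN: int
    opr_nrot: int
    opr_brigid: int
    lip_acc: int
    lip_don: int
    chi0: float
    chi1: float
    chi0_C: float
    chi1_C: float
    chi0v: float
    Kier1: Optional[float]
    Kier2: Optional[float]
    Kier3: Optional[float]
    KierFlex: Optional[float]
    balabanJ: Optional[float]

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


DESCRIPTOR_COLUMNS = [f.name for f in fields(DescriptorVector)]


def _degree(g: MolecularGraph, i: int) -> int:
    d = g.degree(i)
    return d if d > 0 else 1  # isolated heavy atom: define delta = 1


def _valence_delta(g: MolecularGraph, i: int) -> float:
    a = g.atoms[i]
    zv = VALENCE_ELECTRONS[a.element]
    z = ATOMIC_NUMBER[a.element]
    if z <= 10:  # second period
        return float(zv - a.n_h)
    # Kier-Hall correction for higher periods
    return (zv - a.n_h) / (z - zv - 1)


def chi_indices(g: MolecularGraph) -> tuple[float, float, float, float, float]:
    """Connectivity indices ``(chi0, chi1, chi0_C, chi1_C, chi0v)``.

    chi0 sums ``delta_i**-0.5`` over atoms, chi1 sums
    ``(delta_i*delta_j)**-0.5`` over bonds, with delta the heavy-atom
    degree.  chi0v replaces delta by the valence delta.
    """
    chi0 = chi0_c = chi0v = 0.0
    for i, a in enumerate(g.atoms):
        d = _degree(g, i)
        chi0 += d ** -0.5
        dv = _valence_delta(g, i)
        if dv > 0:
            chi0v += dv ** -0.5
        if a.element == "C":
            chi0_c += d ** -0.5
    chi1 = chi1_c = 0.0
    for b in g.bonds:
        term = (_degree(g, b.i) * _degree(g, b.j)) ** -0.5
        chi1 += term
        if g.atoms[b.i].element == "C" and g.atoms[b.j].element == "C":
            chi1_c += term
    return chi0, chi1, chi0_c, chi1_c, chi0v


def path_count(g: MolecularGraph, length: int) -> int:
    """Number of simple paths with ``length`` bonds (undirected, distinct)."""
    if length == 0:
        return g.n_atoms
    count = 0

    def extend(path: list[int]) -> None:
        nonlocal count
        if len(path) == length + 1:
            count += 1
            return
        for nb in g.neighbors(path[-1]):
            if nb not in path:
                extend(path + [nb])

    for start in range(g.n_atoms):
        extend([start])
    return count // 2


# Kier-Hall alpha contributions: covalent radius ratio to sp3 carbon minus 1.
_KIER_ALPHA = {
    ("C", "sp3"): 0.0, ("C", "sp2"): -0.13, ("C", "sp"): -0.22,
    ("N", "sp3"): -0.04, ("N", "sp2"): -0.20, ("N", "sp"): -0.29,
    ("O", "sp3"): -0.04, ("O", "sp2"): -0.20,
    ("F", "sp3"): -0.07, ("Cl", "sp3"): 0.29, ("Br", "sp3"): 0.48,
    ("I", "sp3"): 0.73, ("S", "sp3"): 0.35, ("P", "sp3"): 0.43,
}


def _hybridization(g: MolecularGraph, i: int) -> str:
    orders = []
    for b in g.bonds:
        if i in (b.i, b.j):
            orders.append(b.order)
    if 3 in orders or orders.count(2) >= 2:
        return "sp"
    if 2 in orders or AROMATIC in orders:
        return "sp2"
    return "sp3"


def _alpha_sum(g: MolecularGraph) -> float:
    total = 0.0
    for i, a in enumerate(g.atoms):
        hyb = _hybridization(g, i)
        total += _KIER_ALPHA.get((a.element, hyb), _KIER_ALPHA.get((a.element, "sp3"), 0.0))
    return total


def kier_indices(
    g: MolecularGraph, alpha: bool = False
) -> tuple[Optional[float], Optional[float], Optional[float], Optional[float]]:
    """Kier shape indices ``(kappa1, kappa2, kappa3, flexibility)``.

    kappa1 = A(A-1)^2/P1^2, kappa2 = (A-1)(A-2)^2/P2^2 and kappa3 uses
    Kier's odd/even-A forms with Pk the simple-path counts; flexibility is
    kappa1*kappa2/A.  With ``alpha=True`` both A and Pk are shifted by the
    heteroatom/hybridization alpha sum.
    """
    a_real = g.n_atoms
    da = _alpha_sum(g) if alpha else 0.0
    A = a_real + da

    def kappa(num: float, pk: int) -> Optional[float]:
        p = pk + da
        if pk <= 0 or p <= 0:
            return None
        return num / (p * p)

    k1 = kappa(A * (A - 1) ** 2, path_count(g, 1)) if a_real >= 2 else None
    k2 = kappa((A - 1) * (A - 2) ** 2, path_count(g, 2)) if a_real >= 3 else None
    if a_real >= 4:
        p3 = path_count(g, 3)
        if a_real % 2 == 1:
            k3 = kappa((A - 1) * (A - 3) ** 2, p3)
        else:
            k3 = kappa((A - 3) * (A - 2) ** 2, p3)
    else:
        k3 = None
    flex = (k1 * k2 / a_real) if (k1 is not None and k2 is not None) else None
    return k1, k2, k3, flex


def _is_amide_cn(g: MolecularGraph, b) -> bool:
    """Amide C-N single bond: the carbon carries a double bond to oxygen."""
    pair = {g.atoms[b.i].element, g.atoms[b.j].element}
    if pair != {"C", "N"}:
        return False
    c_idx = b.i if g.atoms[b.i].element == "C" else b.j
    for other in g.bonds:
        if other.order == 2 and c_idx in (other.i, other.j):
            o_idx = other.j if other.i == c_idx else other.i
            if g.atoms[o_idx].element == "O":
                return True
    return False


def count_descriptors(g: MolecularGraph) -> dict:
    """Count-type descriptors (Lipinski acceptors/donors, rotatable and
    rigid bonds, atom/bond counts, molecular weight).

    ``b_rotN`` counts every acyclic single (incl. aromatic-perceived none:
    aromatic bonds are ring bonds) bond between two non-terminal heavy
    atoms; ``opr_nrot`` additionally excludes amide C-N bonds;
    ``opr_brigid`` counts bonds that are neither rotatable (Oprea rule)
    nor attached to a terminal atom.
    """
    lip_acc = sum(1 for a in g.atoms if a.element in ("N", "O"))
    lip_don = sum(a.n_h for a in g.atoms if a.element in ("N", "O"))
    a_nH = sum(a.n_h for a in g.atoms)
    a_nC = sum(1 for a in g.atoms if a.element == "C")
    a_nO = sum(1 for a in g.atoms if a.element == "O")
    weight = sum(ATOMIC_MASS[a.element] + a.n_h * ATOMIC_MASS["H"] for a in g.atoms)

    b_count = g.n_bonds
    b_single = sum(1 for b in g.bonds if b.order in (1, AROMATIC))
    b_double = sum(1 for b in g.bonds if b.order == 2)

    b_rotn = opr_nrot = opr_brigid = 0
    for b in g.bonds:
        terminal = g.degree(b.i) == 1 or g.degree(b.j) == 1
        rotatable_simple = b.order == 1 and not b.in_ring and not terminal
        if rotatable_simple:
            b_rotn += 1
        rotatable_oprea = rotatable_simple and not _is_amide_cn(g, b)
        if rotatable_oprea:
            opr_nrot += 1
        elif not terminal:
            opr_brigid += 1
    return {
        "weight": weight, "a_nH": a_nH, "a_nC": a_nC, "a_nO": a_nO,
        "b_count": b_count, "b_single": b_single, "b_double": b_double,
        "b_rotN": b_rotn, "opr_nrot": opr_nrot, "opr_brigid": opr_brigid,
        "lip_acc": lip_acc, "lip_don": lip_don,
    }


def balaban_j(g: MolecularGraph) -> Optional[float]:
    """Balaban distance-connectivity index J.

    J = B/(mu+1) * sum over bonds of (s_i s_j)^-1/2 with s_i the row sum
    of the topological distance matrix, B the bond count and mu the
    cyclomatic number.  ``None`` for a single atom (no bonds).
    """
    n = g.n_atoms
    if g.n_bonds == 0:
        return None
    rows = [b.i for b in g.bonds] + [b.j for b in g.bonds]
    cols = [b.j for b in g.bonds] + [b.i for b in g.bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    dist = shortest_path(adj, method="D", unweighted=True)
    s = dist.sum(axis=1)
    acc = sum((s[b.i] * s[b.j]) ** -0.5 for b in g.bonds)
    return g.n_bonds / (g.cyclomatic_number + 1) * acc


def compute_descriptors(g: MolecularGraph, kier_alpha: bool = False) -> DescriptorVector:
    """Full descriptor vector for one molecule."""
    chi0, chi1, chi0_c, chi1_c, chi0v = chi_indices(g)
    k1, k2, k3, flex = kier_indices(g, alpha=kier_alpha)
    counts = count_descriptors(g)
    return DescriptorVector(
        chi0=chi0, chi1=chi1, chi0_C=chi0_c, chi1_C=chi1_c, chi0v=chi0v,
        Kier1=k1, Kier2=k2, Kier3=k3, KierFlex=flex,
        balabanJ=balaban_j(g),
        **counts,
    )


def descriptor_table(graphs, kier_alpha: bool = False):
    """Descriptor DataFrame, one row per molecule, fixed column order."""
    import pandas as pd

    rows, index = [], []
    for g in graphs:
        rows.append(compute_descriptors(g, kier_alpha=kier_alpha).as_dict())
        index.append(g.label or f"mol{len(index)}")
    df = pd.DataFrame(rows, index=index, columns=DESCRIPTOR_COLUMNS)
    df.index.name = "molecule"
    return df
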