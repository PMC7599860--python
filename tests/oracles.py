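"""Independent brute-force reference implementations used only by tests.

Everything here recomputes descriptor values from first principles
(explicit loops over atoms/bonds/paths, manual Floyd-Warshall), sharing
no code path with the package implementations it checks.
"""

from __future__ import annotations

import itertools
import math

from permqspr.graph import (
    AROMATIC,
    ATOMIC_MASS,
    ATOMIC_NUMBER,
    VALENCE_ELECTRONS,
    MolecularGraph,
)


def degrees_from_bonds(g: MolecularGraph) -> list[int]:
    deg = [0] * g.n_atoms
    for b in g.bonds:
        deg[b.i] += 1
        deg[b.j] += 1
    return deg


def brute_chi(g: MolecularGraph):
    deg = [d if d > 0 else 1 for d in degrees_from_bonds(g)]
    chi0 = sum(1.0 / math.sqrt(d) for d in deg)
    chi0_c = sum(
        1.0 / math.sqrt(d)
        for d, a in zip(deg, g.atoms)
        if a.element == "C"
    )
    chi1 = sum(1.0 / math.sqrt(deg[b.i] * deg[b.j]) for b in g.bonds)
    chi1_c = sum(
        1.0 / math.sqrt(deg[b.i] * deg[b.j])
        for b in g.bonds
        if g.atoms[b.i].element == "C" and g.atoms[b.j].element == "C"
    )
    chi0v = 0.0
    for a in g.atoms:
        zv = VALENCE_ELECTRONS[a.element]
        z = ATOMIC_NUMBER[a.element]
        dv = (zv - a.n_h) if z <= 10 else (zv - a.n_h) / (z - zv - 1)
        if dv > 0:
            chi0v += 1.0 / math.sqrt(dv)
    return chi0, chi1, chi0_c, chi1_c, chi0v


def adjacency_set(g: MolecularGraph) -> set[tuple[int, int]]:
    out = set()
    for b in g.bonds:
        out.add((b.i, b.j))
        out.add((b.j, b.i))
    return out


def brute_path_count(g: MolecularGraph, length: int) -> int:
    """Count simple paths of `length` edges by exhaustive enumeration."""
    if length == 0:
        return g.n_atoms
    adj = adjacency_set(g)
    count = 0
    for seq in itertools.permutations(range(g.n_atoms), length + 1):
        if all((seq[i], seq[i + 1]) in adj for i in range(length)):
            count += 1
    return count // 2


def brute_kier(g: MolecularGraph):
    a = g.n_atoms
    p1, p2, p3 = (brute_path_count(g, k) for k in (1, 2, 3))
    k1 = a * (a - 1) ** 2 / p1**2 if a >= 2 and p1 > 0 else None
    k2 = (a - 1) * (a - 2) ** 2 / p2**2 if a >= 3 and p2 > 0 else None
    if a >= 4 and p3 > 0:
        k3 = (a - 1) * (a - 3) ** 2 / p3**2 if a % 2 else (a - 3) * (a - 2) ** 2 / p3**2
    else:
        k3 = None
    flex = k1 * k2 / a if (k1 is not None and k2 is not None) else None
    return k1, k2, k3, flex


def brute_balaban(g: MolecularGraph):
    n = g.n_atoms
    if g.n_bonds == 0:
        return None
    inf = float("inf")
    dist = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for b in g.bonds:
        dist[b.i][b.j] = dist[b.j][b.i] = 1
    for k in range(n):  # Floyd-Warshall
        for i in range(n):
            for j in range(n):
                alt = dist[i][k] + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    s = [sum(row) for row in dist]
    mu = g.n_bonds - n + 1
    total = sum(1.0 / math.sqrt(s[b.i] * s[b.j]) for b in g.bonds)
    return g.n_bonds / (mu + 1) * total


def brute_counts(g: MolecularGraph) -> dict:
    deg = degrees_from_bonds(g)

    def is_amide_cn(b) -> bool:
        elems = {g.atoms[b.i].element, g.atoms[b.j].element}
        if elems != {"C", "N"}:
            return False
        c = b.i if g.atoms[b.i].element == "C" else b.j
        for ob in g.bonds:
            if ob.order == 2 and c in (ob.i, ob.j):
                other = ob.j if ob.i == c else ob.i
                if g.atoms[other].element == "O":
                    return True
        return False

    b_rotn = opr_nrot = opr_brigid = 0
    for b in g.bonds:
        terminal = deg[b.i] == 1 or deg[b.j] == 1
        simple_rot = (b.order == 1) and (not b.in_ring) and (not terminal)
        if simple_rot:
            b_rotn += 1
        if simple_rot and not is_amide_cn(b):
            opr_nrot += 1
        elif not terminal:
            opr_brigid += 1
    return {
        "weight": sum(
            ATOMIC_MASS[a.element] + a.n_h * ATOMIC_MASS["H"] for a in g.atoms
        ),
        "a_nH": sum(a.n_h for a in g.atoms),
        "a_nC": sum(a.element == "C" for a in g.atoms),
        "a_nO": sum(a.element == "O" for a in g.atoms),
        "b_count": len(g.bonds),
        "b_single": sum(b.order in (1, AROMATIC) for b in g.bonds),
        "b_double": sum(b.order == 2 for b in g.bonds),
        "b_rotN": b_rotn,
        "opr_nrot": opr_nrot,
        "opr_brigid": opr_brigid,
        "lip_acc": sum(a.element in ("N", "O") for a in g.atoms),
        "lip_don": sum(a.n_h for a in g.atoms if a.element in ("N", "O")),
    }
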