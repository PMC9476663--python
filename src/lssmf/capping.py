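"""Realize fragments as capped molecules.

Every bond that leaves a fragment component's group set is replaced by a
bond to a hydrogen placed along the severed bond vector:

    X_cap = X_i + rho * (X_j - X_i),   rho = (r_i + r_H) / (r_i + r_j)

where i is the retained (anchor) atom and j the removed one, so the cap
C–H distance scales with the expected bond-length ratio (a severed C–C at
1.54 Å yields a 1.084 Å C–H cap). Across a valid bonded plan the signed
cap count vanishes: hydrogens added to +1 fragments are exactly matched by
hydrogens added to -1 fragments, which is what lets cap energies cancel in
the assembled total.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .connectivity import GroupGraph
from .elements import DEFAULT_TABLE, ElementTable
from .errors import GeometryError, PlanError
from .fragments import SignedFragment
from .molecule import Atom, Molecule

CAP_ELEMENT = "H"


def place_cap(
    anchor_position: np.ndarray,
    anchor_element: str,
    removed_position: np.ndarray,
    removed_element: str,
    table: ElementTable = DEFAULT_TABLE,
) -> np.ndarray:
    """Cap-hydrogen position along the severed bond vector."""
    xi = np.asarray(anchor_position, dtype=float)
    xj = np.asarray(removed_position, dtype=float)
    if np.linalg.norm(xj - xi) < 1e-8:
        raise GeometryError("cap placement: anchor and removed atoms coincide")
    ri = table.radius(anchor_element)
    rj = table.radius(removed_element)
    rh = table.radius(CAP_ELEMENT)
    rho = (ri + rh) / (ri + rj)
    return xi + rho * (xj - xi)


@dataclass(frozen=True)
class Cap:
    """A placed link hydrogen: position plus the severed bond it replaces."""

    position: np.ndarray
    anchor: int  # original index of the retained atom
    replaced: int  # original index of the removed atom


@dataclass
class CappedFragment:
    """A realized fragment: real atoms (original indices) plus cap hydrogens.

    ``group_of`` maps each real atom's original index to its group id, which
    group-resolved backends (the toy calculator) need; file-based backends
    only see the element/position list.
    """

    fragment: SignedFragment | None
    real_atoms: list[Atom]
    caps: list[Cap]
    group_of: dict[int, int]

    @property
    def n_atoms(self) -> int:
        return len(self.real_atoms) + len(self.caps)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.real_atoms] + [CAP_ELEMENT] * len(self.caps)

    @property
    def positions(self) -> np.ndarray:
        rows = [a.position for a in self.real_atoms] + [c.position for c in self.caps]
        return np.array(rows).reshape(-1, 3)

    def formula(self) -> Counter:
        """Element multiset including cap hydrogens."""
        out = Counter(a.element for a in self.real_atoms)
        out[CAP_ELEMENT] += len(self.caps)
        return out

    def group_positions(self, g: int) -> np.ndarray:
        rows = [a.position for a in self.real_atoms if self.group_of[a.index] == g]
        return np.array(rows).reshape(-1, 3)

    @property
    def group_ids(self) -> list[int]:
        return sorted(set(self.group_of.values()))

    def as_molecule(self, name: str = "") -> Molecule:
        atoms = [
            Atom(k, el, pos)
            for k, (el, pos) in enumerate(zip(self.elements, self.positions))
        ]
        return Molecule(atoms, name=name, provenance="capped fragment")


def severed_bonds(
    components: Iterable[frozenset[int]], graph: GroupGraph
) -> list[tuple[int, int]]:
    """(anchor, removed) original atom pairs for bonds leaving each component."""
    out: list[tuple[int, int]] = []
    for comp in components:
        for g in sorted(comp):
            for h in sorted(graph.neighbors(g)):
                if h in comp:
                    continue
                for (i, j) in graph.severed_pairs(g, h):
                    out.append((i, j))
    return sorted(out)


def cap_count(fragment: SignedFragment, graph: GroupGraph) -> int:
    return len(severed_bonds(fragment.components, graph))


def realize_fragment(
    fragment: SignedFragment,
    graph: GroupGraph,
    table: ElementTable = DEFAULT_TABLE,
) -> CappedFragment:
    """Real atoms of the member groups plus one cap per severed bond per
    component, in canonical order (real atoms by original index, caps last)."""
    return realize_components(fragment.components, graph, table, fragment=fragment)


def realize_components(
    components: Sequence[frozenset[int]],
    graph: GroupGraph,
    table: ElementTable = DEFAULT_TABLE,
    fragment: SignedFragment | None = None,
) -> CappedFragment:
    mol = graph.molecule
    if mol is None:
        raise ValueError("group graph carries no molecule; fragments cannot be realized")
    members = sorted(frozenset().union(*components))
    atom_ids = sorted(i for g in members for i in graph.group_atoms(g))
    group_of = {i: g for g in members for i in graph.group_atoms(g)}
    real_atoms = [mol.atoms[i] for i in atom_ids]
    caps = [
        Cap(
            position=place_cap(
                mol.atoms[i].position,
                mol.atoms[i].element,
                mol.atoms[j].position,
                mol.atoms[j].element,
                table,
            ),
            anchor=i,
            replaced=j,
        )
        for (i, j) in severed_bonds(components, graph)
    ]
    return CappedFragment(fragment=fragment, real_atoms=real_atoms, caps=caps, group_of=group_of)


def whole_molecule(graph: GroupGraph) -> CappedFragment:
    """The uncapped whole molecule as a CappedFragment (for direct energies)."""
    mol = graph.molecule
    if mol is None:
        raise ValueError("group graph carries no molecule")
    group_of = {
        i: g for g in range(graph.n_groups) for i in graph.group_atoms(g)
    }
    return CappedFragment(
        fragment=None, real_atoms=list(mol.atoms), caps=[], group_of=group_of
    )


def cap_balance(bonded: Sequence[SignedFragment], graph: GroupGraph) -> int:
    """Signed cap-hydrogen count over the bonded plan; must be zero.

    Raises PlanError otherwise — a nonzero value means cap energies would
    not cancel in the assembled total.
    """
    total = sum(f.coefficient * cap_count(f, graph) for f in bonded)
    if total != 0:
        raise PlanError(f"signed cap balance is {total:+d}, expected 0")
    return total


def signed_formula(
    fragments: Sequence[SignedFragment], graph: GroupGraph
) -> Counter:
    """Signed element multiset of the realized bonded plan.

    For a balanced plan this equals the molecule's formula: groups net once
    and caps net zero.
    """
    table = DEFAULT_TABLE
    out: Counter = Counter()
    for f in fragments:
        capped = realize_fragment(f, graph, table)
        for el, n in capped.formula().items():
            out[el] += f.coefficient * n
    return Counter({el: n for el, n in out.items() if n != 0})
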