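"""Bond perception, group partitioning, and the group connectivity graph.

Bond orders come from interatomic distances compared against sums of
covalent radii with configurable slacks. Groups — the elementary units of
the fragmentation — are the connected components of the heavy-atom graph
restricted to multiple (order >= 2) bonds, each carrying its attached
hydrogens; in a saturated alkane every carbon is therefore its own group,
while an aromatic ring merges into a single group. The group graph records
which groups are joined by single bonds and exactly which atom pairs those
severed bonds involve, which is what hydrogen capping needs later.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .elements import DEFAULT_TABLE, ElementTable
from .errors import AssignmentError, GeometryError
from .molecule import MIN_PAIR_DISTANCE, Molecule


@dataclass(frozen=True)
class BondTolerances:
    """Distance slacks (Å) for single/double/triple bond classification plus
    the nonbonded cutoff, carried here so one object configures a run.

    An i–j pair at distance R with radius sum S = r_i + r_j is classified
    order 1 if R < S + delta_sb, tightened to 2 if R < S - delta_db and to 3
    if R < S - delta_tb. Defaults are calibrated to textbook carbon bond
    lengths (1.54 single, ~1.39 aromatic, 1.33 double, 1.20 triple).
    """

    delta_sb: float = 0.40
    delta_db: float = 0.05
    delta_tb: float = 0.20
    delta_nb: float = 10.0

    def __post_init__(self) -> None:
        if not self.delta_sb > 0:
            raise ValueError(f"delta_sb must be > 0, got {self.delta_sb}")
        if not (self.delta_tb > self.delta_db >= 0):
            raise ValueError(
                f"need delta_tb > delta_db >= 0, got "
                f"delta_tb={self.delta_tb}, delta_db={self.delta_db}"
            )


@dataclass
class BondOrderMatrix:
    """Symmetric atom x atom integer bond orders in {0, 1, 2, 3}."""

    order: np.ndarray

    def __post_init__(self) -> None:
        o = np.asarray(self.order)
        if o.ndim != 2 or o.shape[0] != o.shape[1]:
            raise ValueError("bond order matrix must be square")
        if not np.array_equal(o, o.T) or np.any(np.diag(o) != 0):
            raise ValueError("bond order matrix must be symmetric with zero diagonal")
        self.order = o.astype(int)

    def neighbors(self, i: int, min_order: int = 1) -> np.ndarray:
        return np.flatnonzero(self.order[i] >= min_order)


def perceive_bonds(
    molecule: Molecule,
    table: ElementTable = DEFAULT_TABLE,
    tol: BondTolerances = BondTolerances(),
) -> BondOrderMatrix:
    """Classify every atom pair by distance vs covalent-radius sums.

    Later (tighter) conditions overwrite earlier ones, so a short pair ends
    up with the highest order whose threshold it beats.
    """
    n = molecule.n_atoms
    if n == 1:
        return BondOrderMatrix(np.zeros((1, 1), dtype=int))
    dist = squareform(pdist(molecule.positions))
    off = ~np.eye(n, dtype=bool)
    if dist[off].min() < MIN_PAIR_DISTANCE:
        raise GeometryError(
            f"{molecule.name or 'molecule'}: atom pair closer than "
            f"{MIN_PAIR_DISTANCE} Å during bond perception"
        )
    radii = np.array([table.radius(el) for el in molecule.elements])
    rsum = radii[:, None] + radii[None, :]
    order = np.zeros((n, n), dtype=int)
    order[dist < rsum + tol.delta_sb] = 1
    order[dist < rsum - tol.delta_db] = 2
    order[dist < rsum - tol.delta_tb] = 3
    np.fill_diagonal(order, 0)
    bonds = BondOrderMatrix(order)
    _warn_multivalent_hydrogens(molecule, bonds)
    return bonds


def _warn_multivalent_hydrogens(molecule: Molecule, bonds: BondOrderMatrix) -> None:
    for i, el in enumerate(molecule.elements):
        if el == "H" and (bonds.order[i] > 0).sum() > 1:
            warnings.warn(
                f"hydrogen atom {i} has {(bonds.order[i] > 0).sum()} bonds; "
                "geometry may be strained or mis-perceived",
                stacklevel=3,
            )
            break


@dataclass(frozen=True)
class Group:
    """One fragmentation group: heavy atoms merged by multiple bonds, plus
    the hydrogens attached to them."""

    id: int
    heavy_atoms: frozenset[int]
    hydrogens: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.heavy_atoms:
            raise ValueError(f"group {self.id}: heavy_atoms must be nonempty")

    @property
    def atoms(self) -> frozenset[int]:
        return self.heavy_atoms | self.hydrogens


def assign_groups(molecule: Molecule, bonds: BondOrderMatrix) -> list[Group]:
    """Partition atoms into groups.

    Heavy atoms are grouped as connected components over order >= 2 bonds,
    so every singly-bonded heavy atom stands alone. Each hydrogen joins the
    group of a bonded heavy atom (the nearest one if several; ties go to the
    lowest atom index). Group ids follow first appearance of each group's
    lowest-index heavy atom.
    """
    elements = molecule.elements
    heavy = [i for i, el in enumerate(elements) if el != "H"]
    if not heavy:
        raise AssignmentError("molecule has no heavy atoms; cannot form groups")
    g = nx.Graph()
    g.add_nodes_from(heavy)
    order = bonds.order
    for i in heavy:
        for j in heavy:
            if j > i and order[i, j] >= 2:
                g.add_edge(i, j)
    components = sorted(nx.connected_components(g), key=min)
    heavy_to_group: dict[int, int] = {}
    for gid, comp in enumerate(components):
        for i in comp:
            heavy_to_group[i] = gid
    for i in heavy:
        if not np.any(order[i] >= 1):
            warnings.warn(f"heavy atom {i} ({elements[i]}) has no bonds; it forms its own group")
    hydrogens_of: dict[int, set[int]] = {gid: set() for gid in range(len(components))}
    pos = molecule.positions
    for i, el in enumerate(elements):
        if el != "H":
            continue
        partners = [j for j in np.flatnonzero(order[i] >= 1) if elements[j] != "H"]
        if not partners:
            raise AssignmentError(
                f"hydrogen atom {i} is bonded to no heavy atom; cannot assign a group"
            )
        j = min(partners, key=lambda j: (float(np.linalg.norm(pos[i] - pos[j])), j))
        hydrogens_of[heavy_to_group[j]].add(i)
    return [
        Group(gid, frozenset(comp), frozenset(hydrogens_of[gid]))
        for gid, comp in enumerate(components)
    ]


@dataclass
class GroupGraph:
    """Group-level connectivity: which groups are singly bonded to which,
    and through which atom pairs (the bonds that capping will sever)."""

    groups: list[Group]
    adjacency: np.ndarray
    severed_atoms: Mapping[tuple[int, int], tuple[tuple[int, int], ...]]
    molecule: Molecule | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.any(np.diag(a) != 0):
            raise ValueError("group adjacency must be symmetric with zero diagonal")
        self.adjacency = a.astype(int)
        for (x, y) in self.severed_atoms:
            if self.adjacency[x, y] != 1:
                raise ValueError(f"severed atoms listed for non-adjacent groups {x},{y}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def neighbors(self, g: int) -> frozenset[int]:
        return frozenset(int(h) for h in np.flatnonzero(self.adjacency[g]))

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [
            (a, b)
            for a in range(self.n_groups)
            for b in range(a + 1, self.n_groups)
            if self.adjacency[a, b]
        ]

    def severed_pairs(self, a: int, b: int) -> tuple[tuple[int, int], ...]:
        """Bonded atom pairs (i in a, j in b) for adjacent groups a, b."""
        if a < b:
            return self.severed_atoms[(a, b)]
        return tuple((j, i) for (i, j) in self.severed_atoms[(b, a)])

    @property
    def caps_per_group(self) -> dict[int, int]:
        """Severed-bond count each group would incur if isolated."""
        out = {g: 0 for g in range(self.n_groups)}
        for (a, b), pairs in self.severed_atoms.items():
            out[a] += len(pairs)
            out[b] += len(pairs)
        return out

    def group_atoms(self, g: int) -> frozenset[int]:
        return self.groups[g].atoms

    @classmethod
    def from_edges(
        cls, n_groups: int, edges: Iterable[tuple[int, int]]
    ) -> "GroupGraph":
        """Abstract group graph (one placeholder atom per group); used where
        only the topology matters, e.g. coefficient-algebra checks."""
        adj = np.zeros((n_groups, n_groups), dtype=int)
        severed: dict[tuple[int, int], tuple[tuple[int, int], ...]] = {}
        for a, b in edges:
            a, b = min(a, b), max(a, b)
            adj[a, b] = adj[b, a] = 1
            severed[(a, b)] = ((a, b),)
        groups = [Group(g, frozenset({g})) for g in range(n_groups)]
        return cls(groups, adj, severed)


def build_group_graph(
    molecule: Molecule, bonds: BondOrderMatrix, groups: Sequence[Group]
) -> GroupGraph:
    """Adjacency over order-1 bonds between heavy atoms of distinct groups,
    with the severed atom pairs recorded per adjacent group pair."""
    atom_to_group: dict[int, int] = {}
    for grp in groups:
        for i in grp.atoms:
            if i in atom_to_group:
                raise AssignmentError(f"atom {i} assigned to more than one group")
            atom_to_group[i] = grp.id
    if len(atom_to_group) != molecule.n_atoms:
        missing = set(range(molecule.n_atoms)) - set(atom_to_group)
        raise AssignmentError(f"groups do not partition the atoms; missing {sorted(missing)}")
    n = len(groups)
    adj = np.zeros((n, n), dtype=int)
    severed: dict[tuple[int, int], list[tuple[int, int]]] = {}
    elements = molecule.elements
    order = bonds.order
    heavy = [i for i in range(molecule.n_atoms) if elements[i] != "H"]
    for i in heavy:
        for j in heavy:
            if j <= i or order[i, j] != 1:
                continue
            a, b = atom_to_group[i], atom_to_group[j]
            if a == b:
                continue
            (x, y), (p, q) = ((a, b), (i, j)) if a < b else ((b, a), (j, i))
            adj[x, y] = adj[y, x] = 1
            severed.setdefault((x, y), []).append((p, q))
    return GroupGraph(
        list(groups),
        adj,
        {k: tuple(sorted(v)) for k, v in severed.items()},
        molecule=molecule,
    )


def perceive_and_group(
    molecule: Molecule,
    table: ElementTable = DEFAULT_TABLE,
    tol: BondTolerances = BondTolerances(),
) -> GroupGraph:
    """Convenience: bonds -> groups -> group graph in one call."""
    bonds = perceive_bonds(molecule, table, tol)
    groups = assign_groups(molecule, bonds)
    return build_group_graph(molecule, bonds, groups)


def bonded_domain(graph: GroupGraph, g: int) -> frozenset[int]:
    """Groups directly bonded to g (g itself excluded)."""
    if not 0 <= g < graph.n_groups:
        raise ValueError(f"group id {g} out of range 0..{graph.n_groups - 1}")
    return graph.neighbors(g)


def nonbonded_domain(
    graph: GroupGraph,
    g: int,
    settings: "NBSettings",
    table: ElementTable = DEFAULT_TABLE,
) -> frozenset[int]:
    """Groups neither equal nor adjacent to g that pass the nonbonded cutoff."""
    from .nonbonded import pair_within_cutoff  # deferred: avoids import cycle

    nbrs = graph.neighbors(g)
    return frozenset(
        h
        for h in range(graph.n_groups)
        if h != g and h not in nbrs and pair_within_cutoff(graph, g, h, settings, table)
    )
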