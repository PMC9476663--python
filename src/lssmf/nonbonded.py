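"""Nonbonded fragment generation: dimers, three-body complexes, cutoffs.

Level 1 forms dimers of capped groups for every pair of groups that never
co-occurs in a bonded fragment and lies within the cutoff. Level 2 forms
three-body complexes (3BC) between a single group and a bonded two-group
fragment, then appends dimer corrections so that the *signed pair coverage*
of the nonbonded plan equals the indicator of allowed in-range pairs — the
invariant that makes the assembled nonbonded energy consistent (and exactly
equal to level 1 under a pairwise-additive potential).

Two cutoff criteria are supported: distance-based elimination (DBE), which
discards a candidate whose closest-atom separation exceeds delta_nb, and
the distance-to-covalent-radii ratio (DCRR), min over cross atom pairs of
R_ij / (r_i + r_j). For carbon-only systems DCRR t equals DBE at
delta_nb = 1.52 * t (6.0 Å ~ DCRR 3.95).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .connectivity import GroupGraph
from .elements import DEFAULT_TABLE, ElementTable
from .fragments import SignedFragment, canonical_order


@dataclass(frozen=True)
class NBSettings:
    """Nonbonded level and cutoff configuration.

    mode 'dbe' uses delta_nb (Å); mode 'dcrr' uses the dimensionless
    dcrr_threshold. A threshold of ``None`` or infinity disables the cutoff
    (every candidate is kept).
    """

    level: Literal[1, 2] = 1
    mode: Literal["dbe", "dcrr"] = "dbe"
    delta_nb: float | None = 10.0
    dcrr_threshold: float | None = None
    #: For a 3BC, apply the cutoff to the single-group <-> two-group-fragment
    #: separation (the default) or to all three pairwise separations.
    cutoff_all_pairs: bool = False

    def __post_init__(self) -> None:
        if self.level not in (1, 2):
            raise ValueError(f"nonbonded level must be 1 or 2, got {self.level}")
        if self.mode not in ("dbe", "dcrr"):
            raise ValueError(f"cutoff mode must be 'dbe' or 'dcrr', got {self.mode!r}")
        thr = self.delta_nb if self.mode == "dbe" else self.dcrr_threshold
        if thr is not None and not thr >= 0:
            raise ValueError(f"cutoff threshold must be >= 0, got {thr}")

    @property
    def threshold(self) -> float:
        thr = self.delta_nb if self.mode == "dbe" else self.dcrr_threshold
        return math.inf if thr is None else thr

    @classmethod
    def no_cutoff(cls, level: int = 1) -> "NBSettings":
        return cls(level=level, mode="dbe", delta_nb=None)


def _group_positions(graph: GroupGraph, g: int) -> np.ndarray:
    mol = graph.molecule
    if mol is None:
        raise ValueError("group graph carries no molecule; distances are undefined")
    idx = sorted(graph.group_atoms(g))
    return mol.positions[idx]


def min_group_distance(graph: GroupGraph, a: int, b: int) -> float:
    """Closest-atom distance (Å) between the real atoms of two groups."""
    if a == b:
        raise ValueError("min_group_distance requires two distinct groups")
    return float(cdist(_group_positions(graph, a), _group_positions(graph, b)).min())


def dcrr_ratio(
    graph: GroupGraph, a: int, b: int, table: ElementTable = DEFAULT_TABLE
) -> float:
    """min over cross atom pairs of R_ij / (r_i + r_j)."""
    if a == b:
        raise ValueError("dcrr_ratio requires two distinct groups")
    mol = graph.molecule
    if mol is None:
        raise ValueError("group graph carries no molecule; distances are undefined")
    ia, ib = sorted(graph.group_atoms(a)), sorted(graph.group_atoms(b))
    dist = cdist(mol.positions[ia], mol.positions[ib])
    ra = np.array([table.radius(mol.elements[i]) for i in ia])
    rb = np.array([table.radius(mol.elements[j]) for j in ib])
    return float((dist / (ra[:, None] + rb[None, :])).min())


def pair_within_cutoff(
    graph: GroupGraph,
    a: int,
    b: int,
    settings: NBSettings,
    table: ElementTable = DEFAULT_TABLE,
) -> bool:
    if math.isinf(settings.threshold):
        return True
    if settings.mode == "dbe":
        return min_group_distance(graph, a, b) <= settings.threshold
    return dcrr_ratio(graph, a, b, table) <= settings.threshold


def _cooccurring_pairs(bonded: Iterable[SignedFragment]) -> set[frozenset[int]]:
    out: set[frozenset[int]] = set()
    for f in bonded:
        groups = sorted(f.groups)
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                out.add(frozenset((a, b)))
    return out


def allowed_pairs(
    bonded: Sequence[SignedFragment],
    graph: GroupGraph,
    settings: NBSettings,
    table: ElementTable = DEFAULT_TABLE,
) -> list[tuple[int, int]]:
    """Group pairs never co-occurring in a bonded fragment, within cutoff."""
    seen = _cooccurring_pairs(bonded)
    out = []
    for a in range(graph.n_groups):
        for b in range(a + 1, graph.n_groups):
            if frozenset((a, b)) in seen:
                continue
            if pair_within_cutoff(graph, a, b, settings, table):
                out.append((a, b))
    return out


def _dimer(a: int, b: int, coefficient: int) -> SignedFragment:
    return SignedFragment(
        groups=frozenset((a, b)),
        coefficient=coefficient,
        kind="nonbonded",
        components=(frozenset((a,)), frozenset((b,))),
    )


def nb_level1(
    bonded: Sequence[SignedFragment],
    graph: GroupGraph,
    settings: NBSettings,
    table: ElementTable = DEFAULT_TABLE,
) -> list[SignedFragment]:
    """One +1 dimer of capped groups per allowed in-range pair."""
    return canonical_order(
        _dimer(a, b, +1) for a, b in allowed_pairs(bonded, graph, settings, table)
    )


def _fragment_group_distance_ok(
    graph: GroupGraph,
    g: int,
    edge: tuple[int, int],
    settings: NBSettings,
    table: ElementTable,
) -> bool:
    if math.isinf(settings.threshold):
        return True
    if settings.cutoff_all_pairs:
        return all(pair_within_cutoff(graph, g, h, settings, table) for h in edge)
    # minimum over the union of the two-group fragment's atoms == min of the
    # two group-to-group minima (same for the DCRR ratio)
    if settings.mode == "dbe":
        d = min(min_group_distance(graph, g, h) for h in edge)
        return d <= settings.threshold
    r = min(dcrr_ratio(graph, g, h, table) for h in edge)
    return r <= settings.threshold


def nb_level2(
    bonded: Sequence[SignedFragment],
    graph: GroupGraph,
    settings: NBSettings,
    table: ElementTable = DEFAULT_TABLE,
) -> list[SignedFragment]:
    """Three-body complexes with dimer renormalization.

    A 3BC pairs a group g with a two-group bonded fragment {j, k} (a group
    graph edge), provided the three groups never co-occur in a bonded
    fragment and g lies within the cutoff of the fragment. Each 3BC covers
    the cross pairs (g,j) and (g,k); dimers with coefficient
    (target - count) then pin the net signed coverage of every cross pair to
    1 if the pair is allowed and in range, else 0.
    """
    cooccur3 = [f.groups for f in bonded if f.size >= 3]
    complexes: list[SignedFragment] = []
    cross_count: dict[frozenset[int], int] = {}
    for a, b in graph.edges:
        edge = frozenset((a, b))
        for g in range(graph.n_groups):
            if g in edge:
                continue
            triple = edge | {g}
            if any(triple <= fg for fg in cooccur3):
                continue
            if not _fragment_group_distance_ok(graph, g, (a, b), settings, table):
                continue
            complexes.append(
                SignedFragment(
                    groups=triple,
                    coefficient=+1,
                    kind="nonbonded",
                    components=(frozenset((g,)), edge),
                )
            )
            for h in (a, b):
                key = frozenset((g, h))
                cross_count[key] = cross_count.get(key, 0) + 1
    targets = {frozenset(p) for p in allowed_pairs(bonded, graph, settings, table)}
    corrections: list[SignedFragment] = []
    for pair in sorted(targets | set(cross_count), key=lambda p: tuple(sorted(p))):
        target = 1 if pair in targets else 0
        c = target - cross_count.get(pair, 0)
        if c != 0:
            a, b = sorted(pair)
            corrections.append(_dimer(a, b, c))
    return canonical_order(complexes) + canonical_order(corrections)


def nonbonded_plan(
    bonded: Sequence[SignedFragment],
    graph: GroupGraph,
    settings: NBSettings,
    table: ElementTable = DEFAULT_TABLE,
) -> list[SignedFragment]:
    if settings.level == 1:
        return nb_level1(bonded, graph, settings, table)
    return nb_level2(bonded, graph, settings, table)


def cross_pair_coverage(
    nonbonded: Iterable[SignedFragment],
) -> dict[frozenset[int], int]:
    """Net signed coverage of group pairs that straddle complex components."""
    out: dict[frozenset[int], int] = {}
    for f in nonbonded:
        comps = f.components
        for i, ca in enumerate(comps):
            for cb in comps[i + 1:]:
                for a in ca:
                    for b in cb:
                        key = frozenset((a, b))
                        out[key] = out.get(key, 0) + f.coefficient
    return out
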