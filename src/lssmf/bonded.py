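"""Level-m bonded fragmentation with signed renormalization coefficients.

Main fragments are all distinct connected induced sets of m+1 groups.
Overlaps between them are compensated by renormalization fragments carrying
signed integer coefficients, computed by intersection-closure with top-down
counting: every set in the closure family must end up covered exactly once
by the fragments that contain it. This makes the chemical-balance rules
(each group counted net once, each co-occurring pair net once, the signed
cap-hydrogen count net zero) provable consequences of the construction
rather than separate checks — though the engine still verifies them.

Enumeration is pruned per seed group by the union of bonded domains (UBD):
a ball of ceil(m/2) graph hops around the seed. Any connected set of m+1
groups contains a member within ceil(m/2) hops of all others, so scanning
every seed and keeping only seed-containing sets is provably exhaustive
while the per-seed pool stays small (at level 3 on alkanes, at most 16
groups).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

from .connectivity import GroupGraph
from .errors import PlanError
from .fragments import FragmentationPlan, SignedFragment, canonical_order


def union_bonded_domain(graph: GroupGraph, g: int, m: int = 3) -> frozenset[int]:
    """Groups within ceil(m/2) hops of g, excluding g itself.

    At level 3 this is the classic two-hop UBD: the bonded domain of g plus
    the bonded domains of its members.
    """
    if not 0 <= g < graph.n_groups:
        raise ValueError(f"group id {g} out of range 0..{graph.n_groups - 1}")
    hops = max(1, math.ceil(m / 2))
    ball = {g}
    frontier = {g}
    for _ in range(hops):
        frontier = {h for f in frontier for h in graph.neighbors(f)} - ball
        ball |= frontier
    return frozenset(ball - {g})


def enumerate_main_fragments(graph: GroupGraph, m: int) -> list[frozenset[int]]:
    """All distinct connected induced group sets of size m+1.

    If the molecule has at most m+1 groups the whole molecule is the single
    main fragment.
    """
    if m < 1:
        raise ValueError(f"bonded level m must be >= 1, got {m}")
    n = graph.n_groups
    size = m + 1
    if n <= size:
        return [frozenset(range(n))]
    neighbors = [set(graph.neighbors(g)) for g in range(n)]
    found: set[frozenset[int]] = set()
    for seed in range(n):
        pool = {seed} | union_bonded_domain(graph, seed, m)
        _grow({seed}, seed, pool, neighbors, size, found)
    return sorted(found, key=lambda s: tuple(sorted(s)))


def _grow(
    current: set[int],
    seed: int,
    pool: set[int],
    neighbors: Sequence[set[int]],
    size: int,
    found: set[frozenset[int]],
    _seen: set[frozenset[int]] | None = None,
) -> None:
    if _seen is None:
        _seen = set()
    key = frozenset(current)
    if key in _seen:
        return
    _seen.add(key)
    if len(current) == size:
        found.add(key)
        return
    frontier = {h for g in current for h in neighbors[g] if h in pool} - current
    for h in sorted(frontier):
        current.add(h)
        _grow(current, seed, pool, neighbors, size, found, _seen)
        current.remove(h)


def _connected_components_of(groups: frozenset[int], graph: GroupGraph) -> list[frozenset[int]]:
    remaining = set(groups)
    comps: list[frozenset[int]] = []
    while remaining:
        start = min(remaining)
        comp = {start}
        frontier = {start}
        while frontier:
            frontier = {
                h for f in frontier for h in graph.neighbors(f) if h in remaining
            } - comp
            comp |= frontier
        comps.append(frozenset(comp))
        remaining -= comp
    return comps


def derive_coefficients(
    mains: Sequence[frozenset[int]], graph: GroupGraph
) -> list[SignedFragment]:
    """Main fragments (+1 each) plus signed renormalization fragments.

    The candidate family is the closure of the mains under pairwise
    intersection (disconnected intersections split into connected
    components). Processing the family in decreasing size, each set S gets
    c(S) = 1 - sum of c(T) over family supersets T of S, so that every
    family set is covered exactly once; zero coefficients are dropped.
    """
    if not mains:
        raise PlanError("cannot derive coefficients from an empty main-fragment list")
    mains = [frozenset(s) for s in mains]
    if len(set(mains)) != len(mains):
        raise PlanError("main fragments must be deduplicated")
    family: set[frozenset[int]] = set(mains)
    worklist = list(family)
    while worklist:
        new: set[frozenset[int]] = set()
        for s in worklist:
            for t in family:
                inter = s & t
                if not inter or inter in family or inter in new:
                    continue
                for comp in _connected_components_of(inter, graph):
                    if comp not in family:
                        new.add(comp)
        family |= new
        worklist = list(new)
    ordered = sorted(family, key=lambda s: (-len(s), tuple(sorted(s))))
    coeff: dict[frozenset[int], int] = {}
    for s in ordered:
        covered = sum(c for t, c in coeff.items() if s < t)
        coeff[s] = 1 - covered
    fragments = [
        SignedFragment(groups=s, coefficient=c, kind="bonded")
        for s, c in coeff.items()
        if c != 0
    ]
    return canonical_order(fragments)


def bonded_plan(graph: GroupGraph, m: int) -> list[SignedFragment]:
    """The finalized level-m bonded expansion, canonically ordered."""
    if m < 1:
        raise ValueError(f"bonded level m must be >= 1, got {m}")
    if m > 6:
        warnings.warn(f"bonded level {m} is outside the validated range 1..6")
    mains = enumerate_main_fragments(graph, m)
    fragments = derive_coefficients(mains, graph)
    report = balance_report(fragments, graph)
    if not report["ok"]:
        raise PlanError(f"bonded plan violates chemical balance: {report}")
    return fragments


def pair_cooccurrence(fragments: Iterable[SignedFragment]) -> dict[frozenset[int], int]:
    """Signed count of how often each group pair appears inside a fragment."""
    out: dict[frozenset[int], int] = {}
    for f in fragments:
        groups = sorted(f.groups)
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                key = frozenset((a, b))
                out[key] = out.get(key, 0) + f.coefficient
    return out


def balance_report(
    fragments: Sequence[SignedFragment], graph: GroupGraph
) -> dict:
    """Check group balance (each group covered net once) and pair balance
    (each pair inside any main covered net once, all others net zero)."""
    group_cover = {g: 0 for g in range(graph.n_groups)}
    for f in fragments:
        for g in f.groups:
            group_cover[g] += f.coefficient
    pair_cover = pair_cooccurrence(fragments)
    group_ok = all(v == 1 for v in group_cover.values())
    pair_ok = all(v == 1 for v in pair_cover.values())
    return {
        "ok": group_ok and pair_ok,
        "group_coverage": group_cover,
        "pair_coverage": {tuple(sorted(k)): v for k, v in pair_cover.items()},
    }
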