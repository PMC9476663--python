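"""Signed fragments and the fragmentation plan container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

from .connectivity import GroupGraph

Kind = Literal["bonded", "nonbonded"]


@dataclass(frozen=True)
class SignedFragment:
    """A set of groups entering the energy sum with an integer coefficient.

    ``components`` partitions the group set into the pieces that are capped
    and realized as separate molecules placed together: one component for a
    bonded fragment, two (or more) for a nonbonded complex.
    """

    groups: frozenset[int]
    coefficient: int
    kind: Kind = "bonded"
    components: tuple[frozenset[int], ...] = ()

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("fragment group set must be nonempty")
        if not isinstance(self.coefficient, int) or self.coefficient == 0:
            raise ValueError(
                f"fragment coefficient must be a nonzero integer, got {self.coefficient!r}"
            )
        comps = self.components or (self.groups,)
        object.__setattr__(self, "components", tuple(frozenset(c) for c in comps))
        union = frozenset().union(*self.components)
        total = sum(len(c) for c in self.components)
        if union != self.groups or total != len(self.groups):
            raise ValueError("components must partition the fragment's group set")

    @property
    def size(self) -> int:
        return len(self.groups)

    def sort_key(self) -> tuple:
        return (-len(self.groups), tuple(sorted(self.groups)))

    def label(self) -> str:
        body = "+".join(
            "".join(str(g + 1) for g in sorted(c)) for c in self.components
        )
        return f"{self.coefficient:+d}[{body}]"


def canonical_order(fragments: Iterable[SignedFragment]) -> list[SignedFragment]:
    """Size-descending, then lexicographic on sorted group ids."""
    return sorted(fragments, key=SignedFragment.sort_key)


@dataclass
class FragmentationPlan:
    """The full LSSMF(m, n) plan: bonded expansion plus nonbonded fragments."""

    level_bonded: int
    level_nonbonded: int
    bonded: list[SignedFragment]
    nonbonded: list[SignedFragment]
    graph: GroupGraph

    def __post_init__(self) -> None:
        seen: set[frozenset[int]] = set()
        for f in self.bonded:
            if f.groups in seen:
                raise ValueError(f"duplicate bonded fragment {sorted(f.groups)}")
            seen.add(f.groups)

    @property
    def fragments(self) -> list[SignedFragment]:
        return list(self.bonded) + list(self.nonbonded)

    def size_census(self, kind: Kind = "bonded") -> dict[int, int]:
        """Fragment counts keyed by group count, e.g. {4: 6, 3: 5, 2: 2}."""
        out: dict[int, int] = {}
        for f in self.fragments:
            if f.kind == kind:
                out[f.size] = out.get(f.size, 0) + 1
        return dict(sorted(out.items(), reverse=True))

    def census_string(self, kind: Kind = "bonded") -> str:
        """Human-readable census in the 6F4 + 5F3 + 2F2 style."""
        census = self.size_census(kind)
        return " + ".join(f"{n}F{s}" for s, n in census.items()) or "0"
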