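"""Per-element data: single-bond covalent radii.

Radii are the Cordero et al. (2008) consensus values in Å, one value per
element (the sp3 value for carbon, the low-spin value where the source lists
two). They drive bond perception, the distance-to-covalent-radii ratio
(DCRR) cutoff, and cap-hydrogen placement, so the table must be immutable
for the lifetime of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .errors import ElementLookupError

#: Cordero et al. 2008 covalent radii, Å (H–Kr plus common heavier elements).
CORDERO_RADII: Mapping[str, float] = MappingProxyType({
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "I": 1.39, "Xe": 1.40,
})


def normalize_symbol(symbol: str) -> str:
    """Canonical capitalization for an element symbol ('cl' -> 'Cl')."""
    s = symbol.strip()
    if not s:
        return s
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class ElementTable:
    """Immutable element -> covalent radius (Å) lookup."""

    radii: Mapping[str, float] = field(default_factory=lambda: CORDERO_RADII)

    def __post_init__(self) -> None:
        for el, r in self.radii.items():
            if not r > 0:
                raise ValueError(f"covalent radius for {el!r} must be > 0, got {r}")
        object.__setattr__(self, "radii", MappingProxyType(dict(self.radii)))

    def radius(self, element: str) -> float:
        el = normalize_symbol(element)
        try:
            return self.radii[el]
        except KeyError:
            supported = ", ".join(sorted(self.radii))
            raise ElementLookupError(
                f"no covalent radius for element {element!r}; "
                f"supported: {supported}"
            ) from None

    def __contains__(self, element: str) -> bool:
        return normalize_symbol(element) in self.radii


#: Default table shared by the whole pipeline.
DEFAULT_TABLE = ElementTable()


def covalent_radius(element: str, table: ElementTable = DEFAULT_TABLE) -> float:
    """Covalent radius r_i in Å for an element symbol."""
    return table.radius(element)
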