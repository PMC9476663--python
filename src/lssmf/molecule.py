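"""Molecular geometry container plus XYZ and minimal-PDB input/output.

Coordinates are Cartesian Å throughout; nothing downstream ever converts
units. The XYZ reader is deliberately strict and reports the line number of
the first malformed record, since fragment jobs are emitted back out as XYZ
and a silently mis-read geometry would poison every downstream count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .elements import DEFAULT_TABLE, ElementTable, normalize_symbol
from .errors import GeometryError, ParseError

#: Hard floor on interatomic separation (Å); below this the geometry is
#: considered degenerate.
MIN_PAIR_DISTANCE = 0.1


@dataclass(frozen=True)
class Atom:
    """One atom: 0-based input ordinal, element symbol, position (Å)."""

    index: int
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise GeometryError(
                f"atom {self.index} ({self.element}): position must be a "
                f"finite 3-vector, got {self.position!r}"
            )
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "element", normalize_symbol(self.element))


@dataclass
class Molecule:
    """An ordered list of atoms with a label and a provenance string."""

    atoms: list[Atom]
    name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        for k, a in enumerate(self.atoms):
            if a.index != k:
                raise ValueError(
                    f"atom indices must be dense 0..N-1 in order; "
                    f"slot {k} holds index {a.index}"
                )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of Cartesian positions, Å."""
        return np.array([a.position for a in self.atoms])

    def formula(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.atoms:
            out[a.element] = out.get(a.element, 0) + 1
        return out

    def validate(self, table: ElementTable = DEFAULT_TABLE) -> None:
        """Check element support and the degenerate-geometry guard."""
        for a in self.atoms:
            table.radius(a.element)  # raises ElementLookupError if unknown
        if len(self.atoms) >= 2:
            dmin = pdist(self.positions).min()
            if dmin < MIN_PAIR_DISTANCE:
                raise GeometryError(
                    f"{self.name or 'molecule'}: atom pair closer than "
                    f"{MIN_PAIR_DISTANCE} Å (min distance {dmin:.4f} Å)"
                )

    @classmethod
    def from_arrays(
        cls,
        elements: Sequence[str],
        positions: np.ndarray,
        name: str = "",
        provenance: str = "",
    ) -> "Molecule":
        pos = np.asarray(positions, dtype=float).reshape(len(elements), 3)
        atoms = [Atom(i, el, pos[i]) for i, el in enumerate(elements)]
        return cls(atoms, name=name, provenance=provenance)


def read_xyz(path: str | Path) -> Molecule:
    """Read a standard XYZ file (count line, comment line, element x y z rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: expected an atom count, got {lines[0]!r}") from None
    if count < 1:
        raise ParseError(f"{path}:1: atom count must be >= 1, got {count}")
    comment = lines[1].strip() if len(lines) > 1 else ""
    atoms: list[Atom] = []
    for k in range(count):
        lineno = 3 + k
        if 2 + k >= len(lines) or not lines[2 + k].split():
            raise ParseError(
                f"{path}:{lineno}: declared {count} atoms but file ends at atom {k}"
            )
        fields = lines[2 + k].split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 'element x y z', got {lines[2 + k]!r}")
        el = normalize_symbol(fields[0])
        if el not in DEFAULT_TABLE:
            raise ParseError(f"{path}:{lineno}: unknown element symbol {fields[0]!r}")
        try:
            xyz = [float(v) for v in fields[1:4]]
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: non-numeric coordinate in {lines[2 + k]!r}"
            ) from None
        atoms.append(Atom(k, el, np.array(xyz)))
    return Molecule(atoms, name=comment, provenance=str(path))


def write_xyz(molecule: Molecule, path: str | Path, precision: int = 6) -> None:
    """Write standard XYZ with a fixed float format (deterministic output)."""
    path = Path(path)
    path.write_text(xyz_string(molecule, precision=precision))


def xyz_string(molecule: Molecule, precision: int = 6) -> str:
    fmt = f"%-3s %{precision + 6}.{precision}f %{precision + 6}.{precision}f %{precision + 6}.{precision}f"
    rows = [str(molecule.n_atoms), molecule.name]
    rows += [fmt % (a.element, *a.position) for a in molecule.atoms]
    return "\n".join(rows) + "\n"


def read_pdb(path: str | Path) -> Molecule:
    """Read a minimal PDB subset: ATOM/HETATM elements and coordinates.

    Chains, residues and CONECT records are ignored beyond provenance; for
    alternate locations only the blank or 'A' conformer is kept. Bonds are
    perceived geometrically downstream, so none of the topology records are
    needed.
    """
    import gemmi

    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(structure) == 0:
        raise ParseError(f"{path}: no atoms (no model records)")
    model = structure[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                el = atom.element.name
                if not el or el == "X":
                    raise ParseError(
                        f"{path}: atom {atom.name!r} in residue {residue.name!r} "
                        "has no element information"
                    )
                atoms.append(
                    Atom(len(atoms), el, np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                )
    if not atoms:
        raise ParseError(f"{path}: no atoms")
    return Molecule(atoms, name=path.stem, provenance=str(path))


def read_geometry(path: str | Path) -> Molecule:
    """Dispatch on extension: .xyz or .pdb."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        return read_xyz(path)
    if suffix in (".pdb", ".ent"):
        return read_pdb(path)
    raise ParseError(f"{path}: unsupported geometry format {suffix!r} (use .xyz or .pdb)")
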