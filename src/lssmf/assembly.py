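"""Fragment job emission, energy collection, and total-energy assembly.

The engine never runs an electronic-structure method itself: it writes one
XYZ per distinct capped structure plus a manifest tying fragments to
structures and coefficients, and later combines per-structure energies into

    E_total = E_b + E_nb
    E_b     = sum over bonded fragments of  f_i * E(F_i)
    E_nb    = sum over nonbonded fragments of
              g_mu * [ E(complex) - sum over components E(component) ]

(the 'interaction' convention; a 'raw' switch sums complex energies
unreduced). Identical capped structures — e.g. a monomer shared by many
dimers — are deduplicated, which cannot change the assembled energy.

A built-in toy calculator (per-element energies plus a smooth group-pair
potential, optionally a three-body term) closes the loop for testing: with
a pairwise-additive potential and no cutoff the assembled energy must equal
the direct energy of the whole molecule to machine precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .capping import CappedFragment, realize_components, realize_fragment, whole_molecule
from .connectivity import GroupGraph
from .elements import DEFAULT_TABLE, ElementTable
from .errors import AssemblyError
from .fragments import FragmentationPlan, SignedFragment
from .molecule import xyz_string

HARTREE_TO_KCAL = 627.509

EnergyMode = Literal["interaction", "raw"]

# ---------------------------------------------------------------------------
# toy calculator


@dataclass(frozen=True)
class ToyPotential:
    """Analytic test potential: per-element energies plus smooth group-pair
    (and optionally group-triple) terms on real atoms only.

    Cap hydrogens contribute eps('H') and nothing else, mirroring how link
    atoms are meant to cancel across a balanced plan. The pair term is an
    exponential over cross atom pairs, A * exp(-R / lam): strictly pairwise
    additive, smooth, and decaying, so cutoff behavior is observable. The
    optional three-body term takes the three groups' centroids.
    """

    eps: Mapping[str, float] = field(
        default_factory=lambda: {"H": -0.5, "C": -37.8}
    )
    pair_scale: float = 2.0e-3
    pair_range: float = 2.5
    three_body: Callable[[np.ndarray, np.ndarray, np.ndarray], float] | None = None

    def element_energy(self, element: str) -> float:
        try:
            return self.eps[element]
        except KeyError:
            raise AssemblyError(
                f"toy potential has no per-element energy for {element!r}"
            ) from None

    def pair_energy(self, pos_a: np.ndarray, pos_b: np.ndarray) -> float:
        if self.pair_scale == 0.0:
            return 0.0
        d = cdist(pos_a, pos_b)
        return float(self.pair_scale * np.exp(-d / self.pair_range).sum())


def toy_energy(capped: CappedFragment, potential: ToyPotential = ToyPotential()) -> float:
    """Energy (hartree) of a capped structure under the toy potential."""
    e = sum(potential.element_energy(a.element) for a in capped.real_atoms)
    e += len(capped.caps) * potential.element_energy("H")
    gids = capped.group_ids
    pos = {g: capped.group_positions(g) for g in gids}
    for i, a in enumerate(gids):
        for b in gids[i + 1:]:
            e += potential.pair_energy(pos[a], pos[b])
    if potential.three_body is not None:
        cents = {g: pos[g].mean(axis=0) for g in gids}
        for i, a in enumerate(gids):
            for j, b in enumerate(gids[i + 1:], i + 1):
                for c in gids[j + 1:]:
                    e += potential.three_body(cents[a], cents[b], cents[c])
    return e


def toy_backend(potential: ToyPotential = ToyPotential()) -> Callable[[CappedFragment], float]:
    return lambda capped: toy_energy(capped, potential)


# ---------------------------------------------------------------------------
# realization, deduplication, manifest


def _structure_key(capped: CappedFragment) -> tuple:
    """Content identity of a capped structure (element + rounded positions)."""
    return tuple(
        (el, round(p[0], 6), round(p[1], 6), round(p[2], 6))
        for el, p in zip(capped.elements, capped.positions)
    )


@dataclass
class RealizedFragment:
    fragment: SignedFragment
    complex_id: str
    component_ids: tuple[str, ...]


@dataclass
class RealizedPlan:
    """All distinct capped structures of a plan plus fragment -> structure maps."""

    fragments: list[RealizedFragment]
    structures: dict[str, CappedFragment]

    @classmethod
    def from_plan(
        cls, plan: FragmentationPlan, table: ElementTable = DEFAULT_TABLE
    ) -> "RealizedPlan":
        structures: dict[str, CappedFragment] = {}
        by_key: dict[tuple, str] = {}

        def intern(capped: CappedFragment) -> str:
            key = _structure_key(capped)
            if key not in by_key:
                sid = f"s{len(by_key):05d}"
                by_key[key] = sid
                structures[sid] = capped
            return by_key[key]

        out: list[RealizedFragment] = []
        for frag in plan.fragments:
            cid = intern(realize_fragment(frag, plan.graph, table))
            comp_ids: tuple[str, ...] = ()
            if frag.kind == "nonbonded":
                comp_ids = tuple(
                    intern(realize_components((comp,), plan.graph, table))
                    for comp in frag.components
                )
            out.append(RealizedFragment(frag, cid, comp_ids))
        return cls(out, structures)


def _formula_string(capped: CappedFragment) -> str:
    f = capped.formula()
    return "".join(
        f"{el}{f[el]}" for el in sorted(f, key=lambda e: (e != "C", e))
    )


def emit_jobs(
    plan: FragmentationPlan,
    out_dir: str | Path,
    table: ElementTable = DEFAULT_TABLE,
) -> dict:
    """Write one XYZ per distinct capped structure plus ``manifest.json``.

    Output is deterministic: structure ids follow first appearance in the
    canonically ordered plan, floats use a fixed format, and the manifest
    keys are sorted. Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    realized = RealizedPlan.from_plan(plan, table)
    structures_meta = {}
    for sid, capped in realized.structures.items():
        fname = f"structures/{sid}.xyz"
        mol = capped.as_molecule(name=f"{sid} {_formula_string(capped)}")
        (out_dir / fname).write_text(xyz_string(mol))
        structures_meta[sid] = {
            "file": fname,
            "n_atoms": capped.n_atoms,
            "n_caps": len(capped.caps),
            "formula": _formula_string(capped),
            "groups": {str(g): sorted(
                a.index for a in capped.real_atoms if capped.group_of[a.index] == g
            ) for g in capped.group_ids},
        }
    manifest = {
        "molecule": plan.graph.molecule.name if plan.graph.molecule else "",
        "level_bonded": plan.level_bonded,
        "level_nonbonded": plan.level_nonbonded,
        "fragments": [
            {
                "id": f"{rf.fragment.kind[0]}{k:05d}",
                "kind": rf.fragment.kind,
                "coefficient": rf.fragment.coefficient,
                "groups": sorted(rf.fragment.groups),
                "components": [sorted(c) for c in rf.fragment.components],
                "structure": rf.complex_id,
                "component_structures": list(rf.component_ids),
            }
            for k, rf in enumerate(realized.fragments)
        ],
        "structures": structures_meta,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# energy records and assembly


@dataclass(frozen=True)
class EnergyRecord:
    """One computed energy: structure id, hartree value, backend label."""

    structure_id: str
    energy: float
    source: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise AssemblyError(f"non-finite energy for {self.structure_id}")


def read_results(path: str | Path) -> dict[str, float]:
    """Parse delimited text: 'structure_id energy' per line, '#' comments."""
    energies: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        body = line.split("#", 1)[0].strip()
        if not body:
            continue
        fields = body.replace(",", " ").split()
        if len(fields) < 2:
            raise AssemblyError(f"{path}:{lineno}: expected 'id energy', got {line!r}")
        sid, val = fields[0], float(fields[1])
        if sid in energies and abs(energies[sid] - val) > 1e-10:
            raise AssemblyError(
                f"{path}:{lineno}: conflicting energies for {sid}: "
                f"{energies[sid]} vs {val}"
            )
        energies[sid] = val
    return energies


@dataclass
class Contribution:
    fragment_id: str
    kind: str
    coefficient: int
    energy: float  # the fragment's (interaction) energy, hartree
    signed: float  # coefficient * energy


@dataclass
class EnergyLedger:
    """Assembled energies (hartree) with per-fragment signed contributions."""

    E_b: float
    E_nb: float
    contributions: list[Contribution]
    mode: EnergyMode = "interaction"

    @property
    def E_total(self) -> float:
        return self.E_b + self.E_nb

    def summary(self) -> str:
        lines = [
            f"E_b     = {self.E_b:.10f} Eh",
            f"E_nb    = {self.E_nb:.10f} Eh ({self.E_nb * HARTREE_TO_KCAL:.6f} kcal/mol)",
            f"E_total = {self.E_total:.10f} Eh",
            f"fragments: {len(self.contributions)} ({self.mode} nonbonded convention)",
        ]
        return "\n".join(lines)


def assemble_energy(
    manifest: Mapping,
    energies: Mapping[str, float],
    mode: EnergyMode = "interaction",
) -> EnergyLedger:
    """Combine per-structure energies into E_b, E_nb, E_total."""

    def energy_of(sid: str, frag_id: str) -> float:
        try:
            return energies[sid]
        except KeyError:
            raise AssemblyError(
                f"missing energy record for structure {sid} "
                f"(required by fragment {frag_id})"
            ) from None

    contributions: list[Contribution] = []
    e_b = e_nb = 0.0
    for row in manifest["fragments"]:
        fid, coeff = row["id"], int(row["coefficient"])
        e = energy_of(row["structure"], fid)
        if row["kind"] == "nonbonded" and mode == "interaction":
            e -= sum(energy_of(sid, fid) for sid in row["component_structures"])
        signed = coeff * e
        contributions.append(Contribution(fid, row["kind"], coeff, e, signed))
        if row["kind"] == "bonded":
            e_b += signed
        else:
            e_nb += signed
    return EnergyLedger(E_b=e_b, E_nb=e_nb, contributions=contributions, mode=mode)


def assemble_with_backend(
    plan: FragmentationPlan,
    backend: Callable[[CappedFragment], float],
    mode: EnergyMode = "interaction",
    table: ElementTable = DEFAULT_TABLE,
) -> EnergyLedger:
    """Closed-loop assembly: realize the plan, evaluate every distinct
    structure with ``backend`` (a callable CappedFragment -> hartree), and
    assemble. Used by the toy backend and by tests."""
    realized = RealizedPlan.from_plan(plan, table)
    energies = {sid: backend(capped) for sid, capped in realized.structures.items()}
    contributions: list[Contribution] = []
    e_b = e_nb = 0.0
    for k, rf in enumerate(realized.fragments):
        frag = rf.fragment
        e = energies[rf.complex_id]
        if frag.kind == "nonbonded" and mode == "interaction":
            e -= sum(energies[sid] for sid in rf.component_ids)
        signed = frag.coefficient * e
        fid = f"{frag.kind[0]}{k:05d}"
        contributions.append(Contribution(fid, frag.kind, frag.coefficient, e, signed))
        if frag.kind == "bonded":
            e_b += signed
        else:
            e_nb += signed
    return EnergyLedger(E_b=e_b, E_nb=e_nb, contributions=contributions, mode=mode)


def direct_energy(
    graph: GroupGraph, potential: ToyPotential = ToyPotential()
) -> float:
    """Toy energy of the whole molecule, for exactness comparisons."""
    return toy_energy(whole_molecule(graph), potential)
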