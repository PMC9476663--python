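"""Deterministic synthetic alkane geometries for tests and demonstrations.

Builds idealized tetrahedral C_nH_{2n+2} geometries from a carbon-tree
skeleton: C–C 1.54 Å, C–H 1.09 Å, 109.47° angles, all-anti (fully
extended) backbones for chains. Branch and terminal-methyl torsions are
relaxed on a deterministic azimuth grid by maximizing the minimum distance
to already-placed atoms, which keeps even the maximally branched 17-carbon
tree (a central carbon bearing four tert-butyl arms) clash-free above the
0.9 Å guard. Optional seeded Gaussian jitter supports robustness tests;
it is off by default.

These fixtures emulate the chain and branched alkane test systems of the
fragmentation method; they are idealized geometries, not optimized ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .molecule import Molecule

TETRAHEDRAL_DEG = float(np.degrees(np.arccos(-1.0 / 3.0)))  # 109.4712

#: Canonical tetrahedral unit directions (root atom substituents).
_T4 = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float) / np.sqrt(3)

#: Minimum allowed interatomic distance in a generated fixture (Å).
MIN_FIXTURE_DISTANCE = 0.9


@dataclass(frozen=True)
class AlkaneSpec:
    """Carbon skeleton as a parent list (root has parent -1) plus geometry
    parameters. The skeleton must be a tree with maximum degree 4."""

    parents: tuple[int, ...]
    cc_bond: float = 1.54
    ch_bond: float = 1.09
    jitter_sigma: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.parents)
        roots = [i for i, p in enumerate(self.parents) if p < 0]
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        degree = [0] * n
        for i, p in enumerate(self.parents):
            if p >= 0:
                if not 0 <= p < n or p == i:
                    raise ValueError(f"invalid parent {p} for carbon {i}")
                degree[i] += 1
                degree[p] += 1
        if any(d > 4 for d in degree):
            raise ValueError(f"carbon degree exceeds 4: {degree}")
        if self.jitter_sigma < 0 or self.jitter_sigma > 0.01:
            raise ValueError("jitter_sigma must be in [0, 0.01] Å")

    @property
    def n_carbons(self) -> int:
        return len(self.parents)

    @classmethod
    def linear(cls, n: int, **kw) -> "AlkaneSpec":
        if n < 1:
            raise ValueError(f"carbon count must be >= 1, got {n}")
        kw.setdefault("name", f"n-C{n}H{2 * n + 2}")
        return cls(parents=(-1,) + tuple(range(n - 1)), **kw)

    @classmethod
    def two_four_dimethylpentane(cls, **kw) -> "AlkaneSpec":
        """Pentane backbone (carbons 0–4) with methyls on carbons 1 and 3."""
        kw.setdefault("name", "2,4-dimethylpentane")
        return cls(parents=(-1, 0, 1, 2, 3, 1, 3), **kw)

    @classmethod
    def tetra_tert_butylmethane(cls, **kw) -> "AlkaneSpec":
        """Maximally branched 17-carbon tree: central carbon, four tert-butyl
        arms (every group reaches the degree-4 maximum)."""
        parents = [-1, 0, 0, 0, 0]
        for q in (1, 2, 3, 4):
            parents += [q, q, q]
        kw.setdefault("name", "tetra-tert-butylmethane")
        return cls(parents=tuple(parents), **kw)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _cone_dirs(u: np.ndarray, ref: np.ndarray, phi0: float) -> list[np.ndarray]:
    """Three unit vectors at the tetrahedral angle from u, azimuths
    phi0 + {0, 120, 240} degrees measured from ref's projection."""
    th = np.radians(TETRAHEDRAL_DEG)
    e1 = ref - np.dot(ref, u) * u
    n = np.linalg.norm(e1)
    if n < 1e-8:
        a = np.array([1.0, 0, 0]) if abs(u[0]) < 0.9 else np.array([0, 1.0, 0])
        e1 = a - np.dot(a, u) * u
        n = np.linalg.norm(e1)
    e1 /= n
    e2 = np.cross(u, e1)
    out = []
    for k in range(3):
        phi = np.radians(phi0 + 120.0 * k)
        out.append(np.cos(th) * u + np.sin(th) * (np.cos(phi) * e1 + np.sin(phi) * e2))
    return out


_PHI_GRID = [k * 15.0 for k in range(24)]  # deterministic azimuth candidates


def generate_branched_alkane(spec: AlkaneSpec) -> Molecule:
    """Breadth-first tetrahedral placement of the carbon tree, hydrogens to
    valence 4, torsions relaxed deterministically (ties prefer phi = 0,
    which keeps unbranched backbones all-anti)."""
    n = spec.n_carbons
    children: list[list[int]] = [[] for _ in range(n)]
    root = 0
    for i, p in enumerate(spec.parents):
        if p < 0:
            root = i
        else:
            children[p].append(i)
    order = [root]
    for i in order:
        order.extend(children[i])
    pos = np.zeros((n, 3))
    frame: list[tuple[np.ndarray, np.ndarray] | None] = [None] * n
    free_dirs: list[list[np.ndarray] | None] = [None] * n
    placed = [root]
    for i in order:
        p = spec.parents[i]
        if p < 0:
            dirs = [np.array(_T4[k]) for k in range(4)]
        else:
            u = _unit(pos[p] - pos[i])
            g = spec.parents[p]
            ref = _unit(pos[p] - pos[g]) if g >= 0 else np.array(_T4[0])
            frame[i] = (u, ref)
            nch = len(children[i])
            if nch == 0:
                continue  # hydrogen torsion decided later
            others = pos[[a for a in placed if a not in (p, i)]]
            best: tuple[float, float, list[np.ndarray]] | None = None
            for phi0 in _PHI_GRID:
                cand_dirs = _cone_dirs(u, ref, phi0)
                cand = pos[i] + spec.cc_bond * np.array(cand_dirs[:nch])
                score = float(cdist(cand, others).min()) if len(others) else np.inf
                if best is None or score > best[0] + 1e-9:
                    best = (score, phi0, cand_dirs)
            dirs = best[2]
        for k, c in enumerate(children[i]):
            pos[c] = pos[i] + spec.cc_bond * dirs[k]
            placed.append(c)
        free_dirs[i] = dirs[len(children[i]):]
    # hydrogens: fixed slots where children exist, relaxed torsion on methyls
    coords: list[np.ndarray] = [pos[i] for i in range(n)]
    for i in order:
        if free_dirs[i] is not None:
            for d in free_dirs[i]:
                coords.append(pos[i] + spec.ch_bond * d)
        else:
            u, ref = frame[i]
            others = np.array(coords)
            best_h: tuple[float, list[np.ndarray]] | None = None
            for phi0 in _PHI_GRID:
                cand = pos[i] + spec.ch_bond * np.array(_cone_dirs(u, ref, phi0))
                d = cdist(cand, others)
                score = float(d[d > 1e-9].min())
                if best_h is None or score > best_h[0] + 1e-9:
                    best_h = (score, _cone_dirs(u, ref, phi0))
            for d in best_h[1]:
                coords.append(pos[i] + spec.ch_bond * d)
    arr = np.array(coords)
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        arr = arr + rng.normal(0.0, spec.jitter_sigma, arr.shape)
    elements = ["C"] * n + ["H"] * (len(arr) - n)
    mol = Molecule.from_arrays(
        elements, arr, name=spec.name or f"C{n}H{len(arr) - n}",
        provenance=f"alkane fixture: parents={list(spec.parents)} seed={spec.seed}",
    )
    dmin = float(pdist(arr).min())
    if dmin < MIN_FIXTURE_DISTANCE:
        raise ValueError(
            f"generated geometry has an atom pair at {dmin:.3f} Å "
            f"(< {MIN_FIXTURE_DISTANCE} Å); skeleton too crowded"
        )
    return mol


def generate_linear_alkane(n: int, **kw) -> Molecule:
    """Extended (all-anti) linear alkane C_nH_{2n+2}."""
    return generate_branched_alkane(AlkaneSpec.linear(n, **kw))
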