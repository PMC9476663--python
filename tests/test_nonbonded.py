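"""Nonbonded fragments: distances, cutoffs, pair coverage, scaling."""

import math

import numpy as np
import pytest

from lssmf import (
    Molecule,
    NBSettings,
    allowed_pairs,
    bonded_plan,
    build_group_graph,
    cross_pair_coverage,
    dcrr_ratio,
    min_group_distance,
    nb_level1,
    nb_level2,
    generate_linear_alkane,
    perceive_and_group,
    perceive_bonds,
)
from lssmf.connectivity import assign_groups


def bare_carbon_chain(n: int, spacing: float = 1.54) -> "GroupGraph":
    """Hydrogen-free carbon chain: each carbon is its own group."""
    mol = Molecule.from_arrays(
        ["C"] * n, [[i * spacing, 0, 0] for i in range(n)], name=f"C{n} chain")
    bonds = perceive_bonds(mol)
    return build_group_graph(mol, bonds, assign_groups(mol, bonds))


def distant_carbon_pair(distance: float):
    mol = Molecule.from_arrays(["C", "C"], [[0, 0, 0], [distance, 0, 0]])
    with pytest.warns(UserWarning):  # isolated atoms each form a group
        bonds = perceive_bonds(mol)
        return build_group_graph(mol, bonds, assign_groups(mol, bonds))


def test_min_group_distance_definition_and_symmetry(heptane_graph):
    d13 = min_group_distance(heptane_graph, 0, 2)
    assert d13 == min_group_distance(heptane_graph, 2, 0)
    # closest atoms of 1,3-groups in an alkane are hydrogens, nearer than C-C
    pos = heptane_graph.molecule.positions
    cc = np.linalg.norm(pos[0] - pos[2])
    assert d13 < cc
    with pytest.raises(ValueError):
        min_group_distance(heptane_graph, 1, 1)


def test_dcrr_calibration_points():
    graph = distant_carbon_pair(6.0)
    assert dcrr_ratio(graph, 0, 1) == pytest.approx(6.0 / 1.52, abs=1e-12)
    graph = distant_carbon_pair(3.04)
    assert dcrr_ratio(graph, 0, 1) == pytest.approx(2.0, abs=1e-12)
    assert dcrr_ratio(graph, 1, 0) == dcrr_ratio(graph, 0, 1)


def test_heptane_allowed_pairs_no_cutoff(heptane_graph):
    bonded = bonded_plan(heptane_graph, 3)
    pairs = allowed_pairs(bonded, heptane_graph, NBSettings.no_cutoff())
    assert sorted((a + 1, b + 1) for a, b in pairs) == [
        (1, 5), (1, 6), (1, 7), (2, 6), (2, 7), (3, 7)]
    dimers = nb_level1(bonded, heptane_graph, NBSettings.no_cutoff())
    assert len(dimers) == 6
    assert all(f.coefficient == 1 and len(f.components) == 2 for f in dimers)


def test_cutoff_removes_far_pairs(heptane_graph):
    bonded = bonded_plan(heptane_graph, 3)
    tight = allowed_pairs(bonded, heptane_graph, NBSettings(delta_nb=4.0))
    loose = allowed_pairs(bonded, heptane_graph, NBSettings.no_cutoff())
    assert set(tight) < set(loose)
    assert all(
        min_group_distance(heptane_graph, a, b) <= 4.0 for a, b in tight)


def test_whole_molecule_plan_has_no_nonbonded(heptane_graph):
    bonded = bonded_plan(heptane_graph, 6)  # 7 groups <= m+1
    assert allowed_pairs(bonded, heptane_graph, NBSettings.no_cutoff()) == []
    assert nb_level2(bonded, heptane_graph, NBSettings.no_cutoff(2)) == []


@pytest.mark.parametrize("level", [1, 2])
@pytest.mark.parametrize("delta", [None, 6.0])
def test_pair_coverage_indicator(heptane_graph, level, delta):
    """Net signed cross-pair coverage equals the allowed in-range indicator."""
    bonded = bonded_plan(heptane_graph, 3)
    settings = NBSettings(level=level, delta_nb=delta)
    target = {frozenset(p) for p in allowed_pairs(bonded, heptane_graph, settings)}
    nbf = (nb_level1 if level == 1 else nb_level2)(bonded, heptane_graph, settings)
    coverage = cross_pair_coverage(nbf)
    assert {k for k, v in coverage.items() if v != 0} == target
    assert all(v == 1 for k, v in coverage.items() if k in target)


def test_dbe_dcrr_equivalence_on_carbon_only_system():
    graph = bare_carbon_chain(12)
    bonded = bonded_plan(graph, 3)
    for delta in (3.0, 6.0, 9.0):
        dbe = allowed_pairs(bonded, graph, NBSettings(mode="dbe", delta_nb=delta))
        dcrr = allowed_pairs(
            bonded, graph,
            NBSettings(mode="dcrr", dcrr_threshold=delta / 1.52))
        assert dbe == dcrr


def test_nb_count_scaling_linear_with_cutoff_quadratic_without():
    counts_cut, counts_free = {}, {}
    for n in (10, 20, 40):
        graph = perceive_and_group(generate_linear_alkane(n))
        bonded = bonded_plan(graph, 3)
        counts_cut[n] = len(nb_level1(bonded, graph, NBSettings(delta_nb=8.0)))
        counts_free[n] = len(nb_level1(bonded, graph, NBSettings.no_cutoff()))
        assert counts_free[n] == (n - 4) * (n - 3) // 2  # all gap >= 4 pairs
    # fixed cutoff: per-group neighborhood saturates -> linear growth
    slope_low = (counts_cut[20] - counts_cut[10]) / 10
    slope_high = (counts_cut[40] - counts_cut[20]) / 20
    assert slope_high == pytest.approx(slope_low, abs=1.0)
    assert counts_free[40] / counts_free[20] > 3.2  # quadratic tail
    assert counts_cut[40] / counts_cut[20] < 2.5


def test_level2_count_reduced_by_cutoff_on_long_chain():
    graph = perceive_and_group(generate_linear_alkane(70))
    bonded = bonded_plan(graph, 3)
    free = nb_level2(bonded, graph, NBSettings.no_cutoff(2))
    cut = nb_level2(bonded, graph, NBSettings(level=2, delta_nb=10.0))
    assert len(cut) < len(free)
    assert len(cut) < 0.5 * len(free)
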