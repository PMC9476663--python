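"""Cap placement, fragment realization, job emission, and energy assembly."""

import numpy as np
import pytest

from lssmf import (
    AlkaneSpec,
    NBSettings,
    SignedFragment,
    ToyPotential,
    assemble_energy,
    assemble_with_backend,
    bonded_plan,
    build_plan,
    cap_balance,
    cap_count,
    direct_energy,
    emit_jobs,
    generate_branched_alkane,
    generate_linear_alkane,
    perceive_and_group,
    place_cap,
    read_results,
    realize_fragment,
    signed_formula,
    toy_backend,
    toy_energy,
    whole_molecule,
)
from lssmf.errors import AssemblyError, GeometryError, PlanError


# --- cap placement --------------------------------------------------------


def test_cap_length_for_severed_cc_bond():
    cap = place_cap([0, 0, 0], "C", [1.54, 0, 0], "C")
    assert np.linalg.norm(cap) == pytest.approx(1.54 * 1.07 / 1.52, abs=1e-12)
    assert np.linalg.norm(cap) == pytest.approx(1.084, abs=1e-3)


def test_cap_identity_when_removing_hydrogen():
    cap = place_cap([0, 0, 0], "C", [1.09, 0, 0], "H")
    np.testing.assert_allclose(cap, [1.09, 0, 0], atol=1e-12)


def test_cap_lies_on_bond_segment():
    anchor, removed = np.array([1.0, 2.0, 3.0]), np.array([2.0, 1.0, 3.5])
    cap = place_cap(anchor, "C", removed, "C")
    t = (cap - anchor) / (removed - anchor)
    assert np.allclose(t, t[0]) and 0 < t[0] < 1


def test_coincident_atoms_raise():
    with pytest.raises(GeometryError):
        place_cap([0, 0, 0], "C", [0, 0, 0], "C")


# --- realization ----------------------------------------------------------


def test_interior_group_caps_to_methane(heptane_graph):
    frag = SignedFragment(groups=frozenset({3}), coefficient=1)
    capped = realize_fragment(frag, heptane_graph)
    assert capped.formula() == {"C": 1, "H": 4}
    assert len(capped.caps) == 2


def test_three_group_window_caps_to_propane(heptane_graph):
    frag = SignedFragment(groups=frozenset({1, 2, 3}), coefficient=1)
    capped = realize_fragment(frag, heptane_graph)
    assert capped.formula() == {"C": 3, "H": 8}
    assert len(capped.caps) == 2


def test_whole_molecule_fragment_has_no_caps(heptane, heptane_graph):
    frag = SignedFragment(groups=frozenset(range(7)), coefficient=1)
    capped = realize_fragment(frag, heptane_graph)
    assert len(capped.caps) == 0
    assert capped.formula() == heptane.formula()


# --- cap balance and formula conservation --------------------------------


def test_heptane_cap_balance_plus6_minus6(heptane_graph):
    plan = bonded_plan(heptane_graph, 3)
    pos = sum(f.coefficient * cap_count(f, heptane_graph) for f in plan if f.coefficient > 0)
    neg = sum(f.coefficient * cap_count(f, heptane_graph) for f in plan if f.coefficient < 0)
    assert (pos, neg) == (6, -6)
    assert cap_balance(plan, heptane_graph) == 0


def test_24dmp_cap_balance_by_size(dmp24_graph):
    plan = bonded_plan(dmp24_graph, 3)
    by_size = {4: 0, 3: 0, 2: 0}
    for f in plan:
        by_size[f.size] += f.coefficient * cap_count(f, dmp24_graph)
    assert by_size == {4: 14, 3: -20, 2: 6}
    assert cap_balance(plan, dmp24_graph) == 0


def test_unbalanced_plan_rejected(heptane_graph):
    bad = [SignedFragment(groups=frozenset({0, 1}), coefficient=1)]
    with pytest.raises(PlanError, match="cap balance"):
        cap_balance(bad, heptane_graph)


@pytest.mark.parametrize("m", [1, 2, 3, 5])
def test_signed_formula_conservation(dmp24, dmp24_graph, m):
    plan = bonded_plan(dmp24_graph, m)
    assert dict(signed_formula(plan, dmp24_graph)) == dmp24.formula()


# --- toy potential --------------------------------------------------------


def test_toy_energy_no_pair_term(heptane_graph):
    pot = ToyPotential(pair_scale=0.0)
    e = toy_energy(whole_molecule(heptane_graph), pot)
    assert e == pytest.approx(7 * (-37.8) + 16 * (-0.5), abs=1e-12)


def test_toy_energy_rigid_motion_invariance(heptane, heptane_graph):
    from lssmf import Molecule

    rng = np.random.default_rng(3)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    moved = Molecule.from_arrays(
        heptane.elements, heptane.positions @ q.T + [1.0, 2.0, 3.0])
    g2 = perceive_and_group(moved)
    assert direct_energy(g2) == pytest.approx(direct_energy(heptane_graph), abs=1e-10)


def test_additive_atom_energies_assemble_exactly(heptane_graph):
    """With no pair term, signed cap counts cancel and E_total = E(M)."""
    pot = ToyPotential(pair_scale=0.0)
    plan = build_plan(heptane_graph.molecule, 3, NBSettings.no_cutoff())
    ledger = assemble_with_backend(plan, toy_backend(pot))
    assert ledger.E_total == pytest.approx(direct_energy(heptane_graph, pot), abs=1e-10)
    assert ledger.E_nb == pytest.approx(0.0, abs=1e-12)


# --- the exactness theorem ------------------------------------------------


@pytest.mark.parametrize("nb_level", [1, 2])
@pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6])
def test_exactness_pairwise_no_cutoff_linear(m, nb_level):
    """Pairwise-additive toy potential, no cutoff: assembled == direct."""
    mol = generate_linear_alkane(20)
    plan = build_plan(mol, m, NBSettings.no_cutoff(nb_level))
    ledger = assemble_with_backend(plan, toy_backend())
    assert abs(ledger.E_total - direct_energy(plan.graph)) < 1e-10


@pytest.mark.parametrize("nb_level", [1, 2])
@pytest.mark.parametrize("m", [1, 3])
def test_exactness_branched(dmp24, m, nb_level):
    plan = build_plan(dmp24, m, NBSettings.no_cutoff(nb_level))
    ledger = assemble_with_backend(plan, toy_backend())
    assert abs(ledger.E_total - direct_energy(plan.graph)) < 1e-10


def test_level2_reproduces_three_body_sum(heptane_graph):
    """NB1 == NB2 under pairwise additivity; with a triple term added,
    NB2 - NB1 equals the three-body sum over formed complexes exactly."""
    mol = heptane_graph.molecule

    def w(c1, c2, c3):
        d = (np.linalg.norm(c1 - c2) + np.linalg.norm(c1 - c3)
             + np.linalg.norm(c2 - c3))
        return 1e-3 * np.exp(-d / 8.0)

    pairwise = ToyPotential()
    with_w = ToyPotential(three_body=w)
    plans = {lv: build_plan(mol, 3, NBSettings.no_cutoff(lv)) for lv in (1, 2)}
    e1p = assemble_with_backend(plans[1], toy_backend(pairwise)).E_total
    e2p = assemble_with_backend(plans[2], toy_backend(pairwise)).E_total
    assert e2p == pytest.approx(e1p, abs=1e-12)

    e1w = assemble_with_backend(plans[1], toy_backend(with_w)).E_total
    e2w = assemble_with_backend(plans[2], toy_backend(with_w)).E_total
    assert e2w != pytest.approx(e1w, abs=1e-9)
    graph = plans[2].graph
    cents = {
        g: np.vstack([mol.positions[i] for i in sorted(graph.group_atoms(g))]).mean(axis=0)
        for g in range(graph.n_groups)
    }
    # bonded plans are identical and dimers have no triples, so the 1->2
    # shift isolates exactly the triple terms of the formed 3BCs
    assert plans[1].bonded == plans[2].bonded
    expected = sum(
        w(*(cents[g] for g in sorted(f.groups)))
        for f in plans[2].nonbonded
        if len(f.components) == 2 and f.size == 3
    )
    assert (e2w - e1w) == pytest.approx(expected, abs=1e-12)


# --- job emission and file-based assembly --------------------------------


def test_emit_is_deterministic_and_deduplicates(tmp_path, heptane_graph):
    plan = build_plan(heptane_graph.molecule, 3, NBSettings.no_cutoff())
    m1 = emit_jobs(plan, tmp_path / "a")
    m2 = emit_jobs(plan, tmp_path / "b")
    assert (tmp_path / "a/manifest.json").read_bytes() == (
        tmp_path / "b/manifest.json").read_bytes()
    # monomer structures shared across dimers: fewer structures than refs
    refs = sum(1 + len(r["component_structures"]) for r in m1["fragments"])
    assert len(m1["structures"]) < refs


def test_file_round_trip_assembly_matches_backend(tmp_path, heptane_graph):
    """Manifest + results-file assembly equals in-memory assembly."""
    from lssmf.assembly import RealizedPlan

    plan = build_plan(heptane_graph.molecule, 3, NBSettings.no_cutoff(2))
    manifest = emit_jobs(plan, tmp_path)
    realized = RealizedPlan.from_plan(plan)
    backend = toy_backend()
    lines = [f"{sid} {backend(c):.15f}" for sid, c in realized.structures.items()]
    results = tmp_path / "results.txt"
    results.write_text("# toy energies\n" + "\n".join(lines) + "\n")
    ledger = assemble_energy(manifest, read_results(results))
    expected = assemble_with_backend(plan, backend)
    assert ledger.E_total == pytest.approx(expected.E_total, abs=1e-10)
    assert ledger.E_b == pytest.approx(expected.E_b, abs=1e-10)


def test_missing_record_names_fragment():
    manifest_like = {
        "fragments": [
            {"id": "b00000", "kind": "bonded", "coefficient": 1,
             "structure": "s99999", "component_structures": []},
        ],
    }
    with pytest.raises(AssemblyError, match="b00000"):
        assemble_energy(manifest_like, {})


def test_conflicting_results_rejected(tmp_path):
    f = tmp_path / "r.txt"
    f.write_text("s00000 -1.0\ns00000 -2.0\n")
    with pytest.raises(AssemblyError, match="conflicting"):
        read_results(f)


def test_single_fragment_total_is_molecule_energy(heptane_graph):
    plan = build_plan(heptane_graph.molecule, 6, NBSettings.no_cutoff())
    assert len(plan.fragments) == 1
    ledger = assemble_with_backend(plan, toy_backend())
    assert ledger.E_total == pytest.approx(direct_energy(heptane_graph), abs=1e-12)
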