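# lssmf — linear-scaling systematic molecular fragmentation

`lssmf` implements the fragment-generation and energy-assembly machinery of
linear-scaling systematic molecular fragmentation, LSSMF(*m*, *n*): a
divide-and-conquer scheme that makes high-level wavefunction methods
(MP2, CCSD, CCSD(T)) applicable to large molecules by replacing one huge
calculation with many small fragment calculations whose energies are
recombined with signed integer coefficients.

It is aimed at quantum-chemistry practitioners who want to *drive* fragment
calculations: the package perceives bonds, partitions a molecule into
groups, generates the bonded and nonbonded fragment expansions, caps
severed bonds with hydrogens, writes one XYZ job per distinct fragment
structure plus a manifest, and assembles the total energy from per-fragment
energies produced by any external engine. A built-in analytic toy
calculator closes the loop so that every stage is testable without a
quantum-chemistry backend.

## The method

A molecule **M** is partitioned into *groups*: maximal sets of heavy atoms
joined by multiple (order ≥ 2) bonds, plus their hydrogens — in an alkane,
each carbon with its hydrogens. The total energy is approximated as

    E(M) ≈ E_b + E_nb

**Bonded part.** At bonded level *m*, the *main fragments* are all distinct
connected sets of *m* + 1 groups. Overlaps are compensated by
*renormalization fragments* with negative (in general, signed integer)
coefficients *f_i*:

    E_b = Σ_i f_i · E(F_i)

The coefficients are derived by closing the main-fragment family under
pairwise intersection and counting top-down so that every set in the family
is covered exactly once. Chemical balance follows: every group is counted
net once, every co-occurring group pair net once, and the signed number of
cap hydrogens is exactly zero. For 2,4-dimethylpentane at level 3 the
expansion is 6F₄ + 5F₃ + 2F₂ (six four-group mains, five three-group and
two two-group renormalization terms).

**Nonbonded part.** Group pairs never co-occurring in a bonded fragment
interact through nonbonded fragments: dimers of capped groups at level
*n* = 1, or three-body complexes (a group plus a bonded two-group fragment)
with dimer renormalization at *n* = 2. Distant candidates are discarded by
distance-based elimination (DBE, closest-atom distance > Δ_nb) or by the
distance-to-covalent-radii ratio (DCRR, min over atom pairs of
R_ij/(r_i+r_j)); with a fixed cutoff both fragment counts grow linearly
with system size.

**Capping.** Each bond leaving a fragment is replaced by a hydrogen placed
along the severed bond vector at X_i + ρ(X_j − X_i) with
ρ = (r_i + r_H)/(r_i + r_j), using Cordero covalent radii.

## Worked example

```sh
$ lssmf generate --preset 24dmp 24dmp.xyz      # idealized 2,4-dimethylpentane
$ lssmf run 24dmp.xyz -m 3 --nb-level 1 --delta-nb 10
groups: 7
bonded: 6F4 + 5F3 + 2F2
nonbonded fragments: 4
E_b     = -272.4999247644 Eh
E_nb    = 0.0177921233 Eh (11.164718 kcal/mol)
E_total = -272.4821326411 Eh
fragments: 17 (interaction nonbonded convention)
```

Each carbon is a group (7 groups); the level-3 bonded plan is the
6F₄ + 5F₃ + 2F₂ expansion; four group pairs are far enough apart to need
nonbonded dimers within the 10 Å cutoff. The energies come from the
built-in toy potential (per-element energies plus a smooth pair term), so
the absolute numbers only demonstrate the assembly arithmetic — with a
pairwise-additive potential and no cutoff, the assembled total reproduces
the direct energy of the whole molecule to < 1e-10 hartree, which the test
suite verifies for all bonded levels 1–6 and both nonbonded levels.

The same stages are available as library calls:

```python
from lssmf import AlkaneSpec, NBSettings, build_plan, generate_branched_alkane

mol = generate_branched_alkane(AlkaneSpec.two_four_dimethylpentane())
plan = build_plan(mol, m=3, nb=NBSettings(level=1, delta_nb=10.0))
print(plan.census_string("bonded"))   # 6F4 + 5F3 + 2F2
```

For a real engine, `lssmf emit <geometry> <dir>` writes per-fragment XYZ
files and `manifest.json`; run the jobs with any program, collect
`structure_id energy` lines into a text file, and
`lssmf assemble --manifest <dir>/manifest.json --results <file>` produces
the energy ledger.

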