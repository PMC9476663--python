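# Methods

## Scope and model

`lssmf` implements energy-based systematic molecular fragmentation with
linear-scaling cutoffs, LSSMF(*m*, *n*). The package covers everything up
to and after the electronic-structure calculation: geometry input, bond
perception, group partitioning, bonded and nonbonded fragment generation
with signed coefficients, hydrogen capping, job emission, and energy
assembly. Electronic-structure methods themselves, embedded point charges
for polar molecules, and the legacy branched-chain scheme that produces
larger fragments (2F₅ + F₃ for 2,4-dimethylpentane) are out of scope; the
engine consumes per-fragment energies from any backend.

## Bond perception and grouping

Bond orders are classified per atom pair from the interatomic distance R
against the covalent-radius sum S = r_i + r_j (Cordero consensus radii,
one value per element, sp3 for carbon):

| condition        | order |
|------------------|-------|
| R < S + Δ_sb     | 1     |
| R < S − Δ_db     | 2     |
| R < S − Δ_tb     | 3     |

Later conditions overwrite earlier ones. Defaults Δ_sb = 0.40 Å,
Δ_db = 0.05 Å, Δ_tb = 0.20 Å are calibrated to textbook carbon–carbon
distances: 1.54 Å single, ~1.39 Å aromatic (order 2, so benzene merges
into one group), 1.33 Å double, 1.20 Å triple. They are configuration, not
constants.

Groups are the connected components of the heavy-atom graph restricted to
order ≥ 2 bonds; singly bonded heavy atoms stand alone, and each hydrogen
joins its (nearest, on ties lowest-index) bonded heavy atom's group. A
hydrogen with no heavy neighbor is an error; an unbonded heavy atom forms
its own group with a warning. Group ids follow first appearance of each
group's lowest-index atom, making the partition and everything downstream
deterministic and invariant under rigid motion of the geometry.

## Bonded expansion

Main fragments at level *m* are all distinct connected induced sets of
*m* + 1 groups. Enumeration runs per seed group over the union of bonded
domains (UBD), a ball of ceil(*m*/2) graph hops around the seed, keeping
only seed-containing sets: any connected set of *m* + 1 groups has a
member whose eccentricity inside it is at most ceil(*m*/2), so the union
over seeds equals exhaustive enumeration (property-tested against a
brute-force oracle on random trees). At level 3 the ball is the classic
two-hop UBD, whose size on alkanes is at most 16 (attained at the central
carbon of tetra-tert-butylmethane).

Renormalization coefficients come from intersection closure: the main
family is closed under pairwise intersection (disconnected intersections
split into connected components — only reachable for cyclic group graphs,
which are accepted but experimental), then processed in decreasing size
with c(S) = 1 − Σ c(T) over family supersets T ⊋ S; zero coefficients are
dropped. Because every family set ends up covered exactly once, group
balance, pair balance, and cap balance are theorems of the construction;
the engine still verifies all three and refuses to emit an unbalanced
plan. Molecules with ≤ *m* + 1 groups collapse to a single +1 fragment.

## Nonbonded expansion

A group pair is *allowed* if no bonded-plan fragment contains both groups.
Level 1 forms one +1 dimer of capped groups per allowed in-range pair.
Level 2 forms all three-body complexes (group ↔ group-graph edge, the
three groups not co-occurring in any bonded fragment, within cutoff), then
appends dimers with coefficient (target − count) per cross pair, where the
target is the allowed-in-range indicator. This pins the signed cross-pair
coverage to the same indicator at both levels, which is what guarantees
that level 2 degenerates to level 1 exactly under a pairwise-additive
potential while capturing genuine three-body terms otherwise.

Cutoffs: DBE discards candidates whose closest-atom distance exceeds
Δ_nb (default 10.0 Å, a deliberately safe value); DCRR uses the
dimensionless min over cross atom pairs of R_ij/(r_i + r_j), equivalent on
carbon-only systems to DBE at Δ_nb = 1.52·threshold (6.0 Å ↔ ~3.95). For a
3BC the criterion is applied between the single group and the two-group
fragment by default (`cutoff_all_pairs` switches to all three pairwise
distances). Beyond-cutoff interactions are neglected entirely, not
approximated.

## Capping and assembly

Each severed bond i–j (i kept, j removed) is replaced by a hydrogen at
X_i + ρ(X_j − X_i), ρ = (r_i + r_H)/(r_i + r_j) — parameter-free and
element-generic; a severed C–C bond at 1.54 Å gives a 1.084 Å C–H cap.
Caps are placed per complex component, so nonbonded complexes are unions
of independently capped units.

Energies are carried in hartree (summaries also report kcal/mol,
factor 627.509). The assembly is

    E_b  = Σ bonded f_i · E(F_i)
    E_nb = Σ nonbonded g_μ · [E(complex μ) − Σ components E(component)]

The interaction-energy convention for E_nb makes far-separated
contributions vanish, consistent with dropping beyond-cutoff terms; a
`raw` mode that sums unreduced complex energies is available as a
configuration switch. Identical capped structures are deduplicated before
job emission (structure identity = element sequence plus coordinates
rounded to 1e-6 Å); deduplication cannot change the assembled energy, and
emitted manifests are byte-reproducible.

## Toy calculator

The built-in backend assigns each element a fixed energy ε(e) (defaults
ε(C) = −37.8, ε(H) = −0.5 hartree, loosely atomic ground-state scale) plus
a smooth group-pair term A·exp(−R/λ) summed over cross atom pairs of real
atoms (defaults A = 2·10⁻³ hartree, λ = 2.5 Å — large enough to be visible
at double precision, decaying over a few bond lengths so cutoff behavior
is observable). Caps contribute ε(H) only. An optional three-body term on
group centroids exercises the level-2 machinery. Under this potential the
engine satisfies an exactness theorem — pairwise-additive potential, no
cutoff, any bonded level, either nonbonded level: assembled E_b + E_nb
equals the direct energy of the whole molecule to < 1e-10 hartree — which
the test suite asserts on linear (n = 20) and branched fixtures. This
validates the combinatorics and assembly arithmetic, not the accuracy of
fragmentation for real electronic structure, which depends on the backend
and on cutoff/level choices.

## Synthetic fixtures

The generator builds idealized tetrahedral alkanes from a carbon-tree
skeleton: C–C 1.54 Å, C–H 1.09 Å, 109.47° angles. Unbranched backbones
are all-anti (fully extended), which makes distance-based cutoff behavior
monotone in chain gap; branch and terminal-methyl torsions are relaxed on
a deterministic 15° azimuth grid by maximizing the minimum distance to
already-placed atoms (ties prefer the anti choice). Optional Gaussian
jitter (σ ≤ 0.01 Å, seeded, off by default) supports robustness tests.
The fixtures emulate the chain (C_nH_{2n+2}) and branched test systems of
the method at idealized — not optimized — geometries; real molecules add
conformational disorder, heteroatoms, and rings, so passing tests
demonstrate correctness of the fragmentation combinatorics and geometry
handling, not chemical accuracy. The maximally branched 17-carbon fixture
(a central carbon with four tert-butyl arms) is sterically strained by
construction; its closest H–H contacts sit just above the 0.9 Å fixture
guard and trigger a multivalent-hydrogen warning during perception, which
is expected and harmless for its purpose (group-graph topology).

## Problem sizes and numerical choices

Tests and the acceptance script run chains up to C70 (fragment counting
only) and full toy-energy assemblies up to C20 at bonded level 6 — sizes
chosen because every combinatorial regime (collapse, chain windows,
branching, cutoff saturation) is already exercised there. Floating-point
choices: XYZ files carry 6 decimals; structure identity rounds to 1e-6 Å;
exactness assertions use 1e-10 hartree; coefficient arithmetic is exact
integer arithmetic throughout. Bonded levels are validated for 1–6
(higher levels warn), nonbonded levels 1–2.

## Known limitations

- Cyclic group graphs (fused rings joined by single bonds) are accepted
  but flagged experimental; ring-specific repair rules are not implemented.
- PDB support is minimal (elements + coordinates, altLoc blank/'A'); no
  protonation or structure preparation, so raw crystallographic inputs
  typically need external hydrogen addition first.
- No embedded charges: polar molecules will fragment correctly but the
  electrostatic environment of each fragment job is vacuum.
- The toy backend is a verification device, not a force field.
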