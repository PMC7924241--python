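# Methods

## The archetype model of disorder

A disordered crystal structure superimposes *n* alternative local
configurations. disorderkit treats each as an **archetype**: a
hypothetical ordered crystal containing one disorder group plus all
shared atoms, at full occupancy, in the experimental unit cell. The
package's central assumptions are:

- the experimental cell and space group are correct and fixed — nothing
  here ever refines or rescales them;
- each archetype is a chemically complete, connected molecule (or set of
  molecules) whose geometry a single-conformer quantum chemical
  optimization can meaningfully relax;
- the crystal field around each archetype is well approximated by a
  shell of symmetry-generated copies of that same archetype, held rigid
  (molecule-in-cluster approximation). Cross-archetype environments are
  not modelled; disorder groups are alternative realities that never
  coexist in one cluster;
- atoms on special positions are treated as fully occupied.

## Cluster construction

The asymmetric unit is first unwrapped: bonds are perceived under the
minimum-image convention (Cordero 2008 covalent radii, tolerance
0.40 Å, hydrogens limited to degree 1) and each connected component is
walked breadth-first, placing every atom at the image nearest an
already-placed neighbour. Environment candidates are all images of the
unwrapped molecules under every expanded space-group operation and
integer lattice translation; the per-axis translation bound is
`ceil((cutoff + molecular diameter) / cell height) + 1`, which
guarantees no neighbour within the cutoff is missed without hard-coding
a range. An image is kept when any of its atoms lies within the cutoff
of any ASU atom (whole molecules only, never fragments). Duplicate
images — possible when molecules sit on special positions — are removed
by comparing element-tagged coordinates rounded to 10⁻⁴ Å, and an image
fully coincident with the ASU itself is excluded.

The optimization loop rebuilds the environment from the *updated* ASU
coordinates before every cycle, so the crystal field follows the
optimization by symmetry. The published protocol runs a fixed 10
cycles; an optional early stop (RMS Cartesian displacement < 0.01 Å
between cycles) is available but off by default.

## Backends

The backend contract is minimal: `(cluster) -> (new ASU Cartesian
coordinates, total energy in Hartree)`, with the environment implicitly
fixed. `XTBBackend` drives an external tight-binding optimizer through a
TURBOMOLE `$coord` file (Bohr; environment atoms flagged `f`) plus a
fixing control block, and is only usable where that executable exists.
`MockBackend` is the deterministic stand-in used by every test: it
returns the geometry unchanged (optionally transformed by a caller-
supplied move function) and scores the cluster with a smooth pairwise
exp-repulsion/`r⁻⁶` potential between ASU and environment atoms,
distance-clipped at 0.5 Å, scaled so that conformer-pair energy
differences land on the few-kJ/mol scale observed for real archetype
pairs. The mock energy is *not* a physical energy; it exists so that
distinct packings get distinct, reproducible numbers.

## Restraints and constraints

Targets are distances in the optimized geometry: `DFIX` for every bond,
`DANG` for every 1–3 pair (a pair closing a three-membered ring is
emitted only as `DFIX`), default s.u. 0.005 throughout. Bond distances
to hydrogen are shrunk by 13.5 % (factor 0.865) because X-ray data
locate the bonding electron density, not the proton. 1–3 targets
involving hydrogen are **recomputed from the repositioned H** (moved
along its bond vector to the scaled distance) rather than scaled
directly: this keeps every bond angle exactly invariant under the
shrink, which is the physically intended correction; the test suite
verifies angle preservation from the emitted targets alone.

Atoms of different archetypes closer than the proximity threshold
(default 0.5 Å, user-overridable) cannot carry independent displacement
parameters. The default treatment is an `EADP` constraint per proximate
pair — the simplest choice and the one that yields physically meaningful
ADPs. `SIMU` similarity restraints (default s.u. 0.02) can replace the
constraints, and `EXYZ` positional constraints can be added, but both
are opt-in: the DFIX/DANG network already encodes the small positional
differences that EXYZ would erase.

All emission is deterministic (restraints grouped per residue under a
`RESI` card, sorted by kind and labels; constraints sorted) and
round-trips losslessly through the bundled instruction-file parser.
Atom names in restraint lines are residue-qualified (`C1_1`), so the
`RESI` cards act as readable group headers rather than carriers of
scope.

## Occupancy bookkeeping

For two archetypes a single free variable suffices: occupancy codes
`10·fv + p` with `21.0` meaning fv₂ and `−21.0` meaning 1 − fv₂. For
n > 2 each archetype receives its own free variable and the emitted
instruction file carries a `SUMP` sum-to-one side condition; the
parameter count still treats only n − 1 of them as independent, since
the side condition removes one degree of freedom. This trades one
formally redundant variable for instruction files that remain plain
SHELXL (no nested arithmetic in occupancy codes).

Parameter counting follows the standard small-molecule convention:
9 per anisotropic atom, 4 per isotropic atom, one overall scale factor,
one per independent occupancy variable; each `EADP` group of g atoms
removes (g−1)·6 or (g−1)·1 ADP parameters and each `EXYZ` group
(g−1)·3 positional ones.

## Energetics and classification

Energies are normalized to one ASU content (1 Hartree =
2625.4996 kJ/mol) before comparison. The thermal window is `RT` with
R = 8.314 J mol⁻¹ K⁻¹ — 2.48 kJ/mol at 298 K. Boltzmann populations are
computed with the minimum-energy shift for numerical safety; at T = 0
all population collapses onto the minimum (ties split equally).

Classification logic: disorder requires conformers of similar energy at
the crystallization temperature (default 298 K, on the assumption that
crystals are usually grown at ambient conditions), so a per-ASU gap
exceeding three times the similarity window (`similarity_factor × RT`,
factor default 1) returns *disorder-unlikely*. Otherwise the
user-supplied barrier decides: *dynamic* when the barrier is within RT
at the working temperature, *static* when above, *barrier-unknown* when
absent. Barriers are never computed here — they come from external
electronic-structure work. The occupancy–energy consistency check
declares a structure *exempt* rather than judged when the occupancy gap
is within a tie band (default 0.05), since near 50/50 occupancies carry
no ranking information.

## Synthetic fixtures

`make_fixture` generates three templates: a monatomic argon P1 crystal
(cluster-geometry edge cases), a generic split-site C–O toy (two- and
three-group heavy-atom disorder), and the workhorse: a propionamide-like
molecule (CH₃CH₂C(=O)NH₂; 5 heavy atoms, 7 H) in a monoclinic P2₁/c
cell (a=7, b=8, c=9 Å, β=102°), hydrogen atoms disordered over two PART
groups related by mirroring through the heavy-atom plane — the classic
up/down deviation from planarity of a nearly planar amide. Geometry
uses idealized bond lengths (C–C 1.52, C=O 1.23, C–N 1.33, C–H 1.09,
N–H 1.01 Å) plus a seeded uniform perturbation (default amplitude
0.02 Å); a given seed reproduces the structure byte-for-byte.

What the fixtures do **not** emulate: real ADP anisotropy (placeholder
values only), diffraction intensities, solvent/assembly disorder with
independent occupancy links, Z′ > 1, and charged species. Passing tests
therefore demonstrate the correctness of the bookkeeping, symmetry,
geometry and energetics machinery — not the refinement quality
obtainable on deposited experimental structures, which additionally
requires reflection data and an external refinement engine.

## Numerical choices

- Operator translations are stored exactly as integer twelfths, so
  operator deduplication and closure checks are float-free.
- Orthogonalization places **a** along x and **b** in the x–y plane;
  fractional coordinates are the single internal representation and
  Cartesian values are always derived on demand. The frac↔cart round
  trip is verified to ≤ 1 × 10⁻¹⁰ Å.
- SHELX coordinates are written to 6 decimals; round-trip tests compare
  at 5 × 10⁻⁷.
- The occupancy decoder follows SHELXL-2018 free-variable semantics:
  code c with |c| ≥ 10 gives fv = ⌊|c|/10⌋, p = |c| − 10·fv, occupancy
  p·fv (c > 0) or p·(1 − fv) (c < 0); fv = 1 means fixed at p.
- Problem sizes throughout the default test and acceptance runs are the
  12-atom archetypes and their ~11-molecule 3.75 Å clusters; the full
  pipeline completes in about a second on one CPU.

## Known limitations

- Bond perception is purely geometric; protonation-state ambiguities
  (e.g. guanidinium vs guanidine) are not resolved automatically — use
  the `extra_bonds`/`removed_bonds` override hooks.
- An environment molecule sharing a special-position atom with the ASU
  would be dropped by the self-coincidence filter; none of the supported
  fixture geometries exercises this case.
- The cluster-charge question for ionic structures is passed through to
  the backend (`XTBBackend(charge=...)`), defaulting to neutral.
- Restraint emission offers an exclude-list, but no automatic selection
  of "important" restraints: it is all-or-excluded.
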