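# Methods

## Core construction

Cores are built in two steps: a conventional unit cell is tiled into a
block that covers the target shape's bounding box (plus one cell of
margin per side), and the block is sculpted by keeping exactly the beads
whose centers pass the shape's analytic inside-test, boundary inclusive.
Center-inclusion is the simplest convention consistent with treating
beads as lattice points; whether the whole bead sphere should lie inside
is a genuinely open choice, and center-inclusion was picked because it
keeps bead counts an exact function of the lattice and shape.

All four motifs are expressed on *orthorhombic* conventional cells so
replication counts separate per axis: primitive (1-point basis), BCC
(2), FCC (4), and HCP on the a × √3·a × c orthorhombic representation of
the hexagonal cell (4-point basis), with the ideal axial ratio
c/a = √(8/3) — the ratio is not dictated by the touching-sphere
convention, so the ideal close-packing value is used. Lattice constants
follow from the bead radius r so nearest neighbors sit exactly 2r apart:
a = 2r (primitive), 4r/√3 (BCC), 2√2·r (FCC), 2r (HCP in-plane). The
tiled block is re-centered on the origin, so a primitive L × L × L block
holds exactly (⌊L/a⌋ + 1)³ beads. Sculpting is deterministic and
idempotent; re-sculpting tolerates a block whose bead span stops up to
one cell short of the analytic bounding box, since near shape vertices
(octahedron tips, pyramid apex) no lattice point reaches the boundary.

Shape conventions: cylinder, rod and pyramid axes run along Z; every
shape is centered at the origin. The **rod** is a cylinder with
hemispherical caps *included in its stated total length* (cylindrical
section L − 2ρ, so L ≥ 2ρ is required, and L = 2ρ degenerates to a
sphere); the alternative — caps appended beyond L — would make "length"
mean different things for cylinder and rod. Surface areas and volumes
are closed forms except the ellipsoid area, which uses the Thomsen
approximation (p = 1.6075, max relative error ≈ 1.1%).

**Surface detection.** A bead is superficial when it has fewer touching
neighbors (within 2r + 10⁻³·r) than the bulk coordination of its lattice
(6/8/12/12). The outward normal is the unit vector from the core's
center of mass to the bead: exact for spheres, an approximation on flat
faces of the other convex shapes (recorded as such); a single-bead core
gets an arbitrary +Z normal, flagged in the model notes.

**Hollow shells** carry no lattice. Beads are placed on a golden-angle
(Fibonacci) spiral — a deterministic quasi-uniform spherical lattice —
with the count fixed by an area budget: each bead claims a hexagonal
packing tile of width 2r, so N = 4πR² / (πr²/η) with η = π/(2√3). All
beads sit exactly at radius R; the spacing is approximate (mean
nearest-neighbor distance ≈ 0.89 × 2r, with some pairs closer), which is
the price of exact radius plus quasi-uniformity. Shells below four beads
are rejected; in practice the radius > bead-radius check fires first.

## Mass assignment

The coarse core must weigh what the real particle weighs, so the user
supplies the bulk density in g/cm³ (19.3 for gold) and the total mass is
density × analytic shape volume, converted at 602.214 amu per
(g/cm³)·nm³, then split equally over the beads. For a hollow shell the
*enclosed* sphere volume is used: the shell stands in for the surface of
a solid particle, and its beads carry that particle's bulk mass. Mass
conservation holds to < 10⁻⁶ relative by construction.

## Elastic network

Lattice cores receive one harmonic bond (Gromacs function type 1,
equilibrium length = current distance = 2r, constant k_b, default
32,500 kJ mol⁻¹ nm⁻²) per unique pair of touching neighbors, giving
interior beads exactly the bulk coordination. Shell beads are bonded to
their six nearest neighbors plus the bead closest to their exact
antipode (quasi-uniform shells have no exact antipodal site); the
antipodal tie keeps the hollow sphere from collapsing. Bonds are
deduplicated as unordered pairs, so a bead can acquire extra bonds by
being some other bead's neighbor — the guarantee is that each bead's own
6 + 1 set is present.

## Anchor selection

N_lig = round(area / grafting density), at least 1, and never more than
the surface bead count. N_lig virtual sites start uniformly at random on
the unit sphere (seeded) and a Metropolis–Hastings walk maximizes
D_u = Σ_{i<j} ‖x_i − x_j‖ under the unit-norm constraints. Distances are
*chordal*: the objective sums distances between points in 3-space, and
chord and geodesic optima coincide for the small-N configurations with
known closed forms. Unstated algorithmic details were fixed once for
robustness and reproducibility: one-site Gaussian tangent proposals with
σ = 0.1 rad followed by renormalization (so the constraint holds after
every move), effective temperature annealed linearly from 0.1 to 0 over
a budget of 2,000·N proposals, and the best-seen configuration returned
— which also guarantees the final D_u never falls below the initial one
for any seed. The optimizer reaches the N = 2 (diameter, D_u = 2) and
N = 4 (regular tetrahedron, D_u = 6√(8/3)) optima well within 1% under
the default budget.

Each site then claims the surface bead minimizing angular distance
(arccos of the dot product with the bead's unit position about the core
center). Contested beads go to the first claimant in site order; losing
sites take their nearest still-available bead, so anchors are always a
bijection onto N_lig distinct surface beads, and a saturated monolayer
(N_lig = surface count) claims every surface bead.

## Morphologies

Labels 1 and 2 select which built ligand each anchor receives.
*Homogeneous*: all label 1. *Random*: exactly round(f_m · N_lig) anchors
get label 1 through a seeded shuffle. *Janus-axis*: the dividing plane
sits at the f_m-quantile of anchor coordinates along the axis — the
round(f_m · N_lig) anchors furthest along the positive axis are ligand 1
— so the ratio controls abundance exactly on any shape. *Stripe-axis*:
n_stripes (≥ 2) equal-width slabs spanning the anchors' coordinate range
alternate labels starting with ligand 1 at the negative end.

## Ligand construction and grafting

A ligand is a connected bead graph whose first bead is the attachment
point. Beads are appended depth-first (longest chain first, so PC1
tracks the backbone) by natural-extension placement: bond length l₀ and
bending angle θ₀ from the parameter table by bead-type lookup, torsion
trans (180°), with sibling branches splayed at 120° offsets. Missing
entries fall back to a collinear continuation at 0.35 nm — a typical CG
bond length, shorter than Martini's 0.47 nm backbone bond as befits an
anchoring link — and every fallback is recorded in the build notes. With
no parameter file at all the chain is exactly collinear. Achieved bonds
and angles match l₀/θ₀ to 10⁻⁶.

Grafting is a rigid motion (internal distances preserved to < 10⁻⁹ nm):
the ligand's first principal component (PC1, oriented from the
attachment bead toward the far end) is rotated onto the anchor's outward
normal, and the attachment bead is set one anchor-bond length beyond the
anchor bead along the normal. That length comes from the (core type,
first-bead type) bond entry when present — the thiol sulfur is treated
as absorbed into the anchor bead, so this bond is the chemisorption link
— else the 0.35 nm default, noted. Finally 20 rotations about PC1 on a
deterministic 18° grid are scored by their minimum distance to the rest
of the system (core plus previously placed ligands, in anchor order) and
the argmax is kept; a deterministic grid rather than random spins keeps
rebuilds bit-identical. A consequence used by the test suite: a
collinear ligand's beads lie exactly on the anchor normal, so a freshly
built particle has zero mean tilt.

## Topology assembly

Core beads are neutral, share the bulk mass, and carry a single
user-chosen type (default the apolar Martini bead C1); ligand masses and
charges are written explicitly per bead. Bonded tuples are enumerated
center-out per ligand copy on the graph extended by the anchor bead:
bonds are edges, angles are 2-paths, dihedrals are 3-paths (canonical
orientation, each tuple once). For a 3-bead chain this gives 3 bonds
(including the anchor bond), 2 angles, 1 dihedral per copy. Parameters
are assigned by symmetric type lookup (AB ≡ BA, ABC ≡ CBA, ABCD ≡ DCBA);
a quadruplet with several stacked dihedral entries emits one term per
entry; anything missing is skipped and itemized, and the report's
accounting is exact: enumerated = assigned + skipped.

Serialization: `.gro`/`.pdb` are written through MDAnalysis (core beads
first, then ligands in anchor order, consistent with the topology
numbering; `.gro` carries nm to three decimals, `.pdb` Å; PDB serials
past 99,999 wrap per convention and are noted). The molecule `.itp`
holds atoms, bonds (harmonic: function type, l₀, k, with the elastic
network appended), angles (θ₀, k), and periodic dihedrals (equilibrium,
amplitude, multiplicity). The `.top` contains exactly one `#include`
line for the nonbonded interaction matrix; a helper can emit a
syntactically valid *synthetic* placeholder matrix (zero Lennard-Jones),
but production runs should point that line at a real force-field file.
`nrexcl` defaults to 1.

## Analysis

G_mono(r) — the normalized cumulative radial distribution of monolayer
beads about the particle center of mass — is the empirical step CDF of
the bead distances (the Dirac-delta integral of the definition evaluated
exactly). The monolayer thickness is the 90%-probability shell,
quantile(0.95) − quantile(0.05), with quantiles by linear interpolation
between order statistics. The center of mass is computed over *core
beads only* by default: the core dominates the mass and the measure then
ignores monolayer fluctuations; `com="all"` switches to the full
particle. Tilt angles are measured between each anchor→bead vector and
the anchor's normal, recomputed per frame from the instantaneous core
center of mass, and averaged over beads, then ligands, then frames;
beads coincident with their anchor are skipped and counted. The radius
of gyration is the mass-weighted RMS distance from the center of mass.
Bootstrap errors resample with replacement at 1% of the sample, 1,000
iterations by default, seeded, and report the standard deviation of the
resample means.

## Synthetic test data

The fixture ligands mirror CG alkylthiol chains under a 4-to-1 mapping —
one-, two-, three-, and five-bead C1 chains of 72 amu per bead, 0.47 nm
bonds, straight 180° angles, with the three-bead chain standing for a
13-carbon thiol whose sulfur is absorbed into the anchor. The jittered
coordinate series emulates MD frames by adding seeded isotropic Gaussian
noise to ligand beads while holding the core fixed (as the elastic
network would). It reproduces *none* of the physics of a real
trajectory — no excluded volume, no bonded restoring forces, no
solvent — so passing analysis tests demonstrates that the estimators are
correct on known distributions, not that the models reproduce
experimental monolayer widths; that comparison requires ~100 ns of MD
with an external engine and is out of scope.

## Problem sizes and numerics

The test suite runs on small cores (spheres of radius 1.0–2.5 nm,
hundreds to a few thousand beads) where every invariant can be checked
by direct enumeration; the capacity check builds the full 18 nm FCC
sphere (~8.8 × 10⁵ beads, about a second). Neighbor tolerance is
10⁻³ × bead radius everywhere; boundary tests are inclusive; tie-breaks
(contested anchors, equal-scoring rotations) go to the first candidate
in deterministic order, so identical inputs give bit-identical models.

## Known limitations

- Crystallographic surface reconstruction, faceted (Wulff) equilibrium
  shapes, and alloyed cores are out of scope.
- Surface normals on flat faces are radial approximations.
- The builder places, but does not energy-minimize, the monolayer; the
  20-rotation clash relief is a heuristic, not a minimizer.
- Force-field correctness of user parameters is not verified; the
  bundled interaction-matrix stub is a syntactic placeholder only.
- Branched ligands are supported structurally (depth-first placement),
  but only linear chains are exercised by the validation suite.
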