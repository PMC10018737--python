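# nanosculpt

Coarse-grained (CG) model builder for monolayer-protected metal
nanoparticles. Molecular-dynamics studies of functionalized metal
nanoparticles larger than ~2 nm are only tractable at CG resolution, but
assembling a simulation-ready model by hand — tens of thousands of core
beads on the right crystal lattice, a ligand shell at a controlled
grafting density and pattern, and a consistent Gromacs topology — is
tedious and error-prone. `nanosculpt` automates it for computational
chemists and biophysicists who run Martini-style simulations of
ligand-coated nanoparticles.

## What it builds

**Cores.** A conventional unit cell of one of four bulk-metal lattices
(primitive cubic, BCC, FCC, HCP) is replicated into a block and sculpted
into one of eight shapes (sphere, ellipsoid, octahedron, cylinder, rod,
rectangular prism, square pyramid, hollow spherical shell). The lattice
constant follows the touching-sphere convention — nearest neighbors sit
exactly two bead radii apart — so interior beads have bulk coordination
6/8/12/12 for primitive/BCC/FCC/HCP. The real particle mass
(bulk density × analytic shape volume) is distributed equally over the
beads, and an elastic network of stiff harmonic bonds between touching
neighbors (default k_b = 32,500 kJ mol⁻¹ nm⁻²) keeps the core rigid.

**Monolayers.** The ligand count is N_lig = area / grafting density
(nm² per ligand). Anchors are picked by spreading N_lig virtual sites on
the unit sphere — maximizing the summed pairwise distance

D_u = Σ_{i<j} ‖x_i − x_j‖  subject to ‖x_i‖ = 1

with a Metropolis–Hastings walk — and claiming, for each site, the
surface bead at minimal angular distance (duplicates fall back to the
nearest available bead). Eight morphologies assign ligand labels:
homogeneous, random, Janus-X/Y/Z, and Stripe-X/Y/Z, with a mixing
fraction f_m and seeded reproducibility. Ligands are grown bead-by-bead
at their equilibrium bond lengths l₀ and angles θ₀ (parsed from a
Gromacs-dialect .itp), rigidly placed so the molecular long axis (PC1)
lies along the anchor's surface normal, and spun through 20 candidate
rotations about PC1 keeping the least-clashing orientation.

**Output.** `.gro` (nm) and `.pdb` (Å) structures, a molecule `.itp`
(atoms, bonds, angles, dihedrals, elastic network), and a `.top` whose
single `#include` line references the nonbonded interaction matrix — swap
force fields by editing that one line. Missing bonded parameters are
never guessed: they are skipped and itemized in the job report.

**Analysis.** The validation statistics: normalized cumulative radial
distribution of monolayer beads G_mono(r), monolayer thickness
r_max − r_min with G_mono(r_min) = 0.05 and G_mono(r_max) = 0.95, ligand
tilt angles against the anchor normals, mass-weighted radius of
gyration, and bootstrap standard errors (1,000 iterations, 1% resamples).

## Worked example

```python
import nanosculpt as ns
from nanosculpt.fixtures import alkyl_ligand_fixture

lattice = ns.LatticeSpec("fcc", bead_radius=0.17)     # gold-like core
shape = ns.ShapeSpec("sphere", (1.5,))                # 3 nm particle
core = ns.build_core(lattice, shape)
ns.identify_surface(core)
print(core.n_beads, len(core.surface_index))          # 531 282

area, volume = ns.shape_geometry(shape)
n_lig = ns.ligand_count(area, grafting_density=0.9)
print(n_lig)                                          # 31

sites = ns.optimize_virtual_sites(n_lig, seed=2)
anchors = ns.map_anchors(sites, core)
ns.label_morphology(anchors, ns.MorphologySpec("random", ratio=0.5, seed=3))

fix = alkyl_ligand_fixture(3)                         # 3-bead alkyl chain
params = ns.parse_itp(fix.write_itp("alkyl.itp"))
built = ns.build_ligand(fix.template, params)
model = ns.graft_ligands(core, anchors, {1: built, 2: built}, params=params)

ns.assign_core_masses(core, bulk_density=19.3)        # g/cm^3
print(f"{core.masses.sum():.4g}")                     # 1.643e+05 (amu)

from nanosculpt.topology import assign_ligand_topology, write_structure, write_topology
doc = assign_ligand_topology(model, params)
write_structure(model, "np.gro", doc)
write_topology(doc, "np.top")

from nanosculpt.analysis import series_from_model, tilt_angles
mean_tilt, _ = tilt_angles(series_from_model(model))
print(f"{mean_tilt:.2e}")                             # 1.74e-07 (degrees)
```

The 531-bead FCC sphere exposes 282 surface beads; 31 anchors carry the
ligands at 0.9 nm² per ligand; the core's beads share 1.643 × 10⁵ amu —
the mass of a solid 3 nm gold sphere — and the freshly built monolayer's
mean tilt angle is zero to floating-point precision, because construction
aligns every ligand axis with its anchor normal.

The same pipeline is available from the shell:

```bash
nanosculpt build --lattice fcc --bead-radius 0.17 --shape sphere --dim 1.5 \
    --grafting-density 0.9 --morphology random --ratio 0.5 --seed 3 \
    --out-prefix np
nanosculpt analyze np.gro --metric thickness --core-beads 531
```

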