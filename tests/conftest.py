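import numpy as np
import pytest

import nanosculpt as ns
from nanosculpt.fixtures import FixtureSpec, alkyl_ligand_fixture, make_ligand_fixture


@pytest.fixture(scope="session")
def fcc_lattice():
    return ns.LatticeSpec("fcc", 0.17)


@pytest.fixture(scope="session")
def small_core(fcc_lattice):
    """FCC sphere of radius 1.5 nm with surface identified (531 beads)."""
    core = ns.build_core(fcc_lattice, ns.ShapeSpec("sphere", (1.5,)))
    ns.identify_surface(core)
    return core


@pytest.fixture(scope="session")
def ligand3(tmp_path_factory):
    """Three-bead alkyl ligand fixture with dihedral, parsed back from disk."""
    fix = make_ligand_fixture(
        FixtureSpec(n_beads=3, dihedral=(180.0, 1.96, 1), name="ALK3")
    )
    path = fix.write_itp(tmp_path_factory.mktemp("itp") / "alk3.itp")
    params = ns.parse_itp(path)
    return fix, params


@pytest.fixture()
def grafted_model(small_core, ligand3):
    """Small homogeneous nanoparticle: 12 collinear 3-bead ligands."""
    fix, params = ligand3
    core = ns.CoreModel(
        positions=small_core.positions.copy(),
        bead_radius=small_core.bead_radius,
        shape=small_core.shape,
        lattice=small_core.lattice,
        surface_index=small_core.surface_index.copy(),
        normals=small_core.normals.copy(),
    )
    sites = ns.optimize_virtual_sites(12, seed=7, budget=4000)
    anchors = ns.map_anchors(sites, core)
    ns.label_morphology(anchors, ns.MorphologySpec("homogeneous"))
    built = ns.build_ligand(fix.template, params)
    model = ns.graft_ligands(core, anchors, {1: built}, params=params)
    ns.assign_core_masses(core, 19.3)
    return model, params
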