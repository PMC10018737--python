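import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

import nanosculpt as ns
from nanosculpt.monolayer import DEFAULT_SPACING, optimize_virtual_sites


def total_distance(points):
    return pdist(points).sum()


@pytest.mark.parametrize(
    "area, density, expected",
    [(314.159, 0.3, 1047), (28.274, 0.3, 94), (5.0, 5.0, 1)],
)
def test_ligand_count_rounds_area_over_footprint(area, density, expected):
    assert ns.ligand_count(area, density) == expected


def test_ligand_count_exceeding_surface_names_both_numbers():
    with pytest.raises(ValueError, match="10 ligands.*3 surface"):
        ns.ligand_count(3.0, 0.3, n_surface=3)


class TestVirtualSites:
    def test_single_site_is_unit_vector(self):
        x = optimize_virtual_sites(1, seed=0)
        assert x.shape == (1, 3)
        assert np.linalg.norm(x[0]) == pytest.approx(1.0)

    def test_two_sites_become_antipodal(self):
        x = optimize_virtual_sites(2, seed=3)
        assert total_distance(x) == pytest.approx(2.0, rel=0.01)

    def test_four_sites_form_regular_tetrahedron(self):
        x = optimize_virtual_sites(4, seed=3)
        assert total_distance(x) == pytest.approx(6 * math.sqrt(8 / 3), rel=0.01)

    @given(seed=st.integers(0, 50), n=st.integers(2, 12))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_unit_constraint_and_monotone_improvement(self, seed, n):
        """Sites stay on the unit sphere and the objective never degrades."""
        x, history = optimize_virtual_sites(
            n, seed=seed, budget=200, return_history=True
        )
        assert np.linalg.norm(x, axis=1) == pytest.approx(1.0, abs=1e-9)
        assert total_distance(x) >= history[0] - 1e-9

    def test_reproducible_for_fixed_seed(self):
        a = optimize_virtual_sites(6, seed=11, budget=500)
        b = optimize_virtual_sites(6, seed=11, budget=500)
        assert np.array_equal(a, b)

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            optimize_virtual_sites(0, seed=0)


class TestMapAnchors:
    def test_aligned_site_claims_that_bead(self, small_core):
        direction = small_core.positions[small_core.surface_index[0]]
        site = direction / np.linalg.norm(direction)
        anchors = ns.map_anchors(site[None, :], small_core)
        assert anchors.anchor_indices[0] == small_core.surface_index[0]

    def test_duplicate_claims_are_exchanged(self, small_core):
        direction = small_core.positions[small_core.surface_index[0]]
        site = direction / np.linalg.norm(direction)
        anchors = ns.map_anchors(np.stack([site, site]), small_core)
        assert len(set(anchors.anchor_indices)) == 2

    def test_saturated_monolayer_claims_every_surface_bead(self, small_core):
        n = len(small_core.surface_index)
        sites = optimize_virtual_sites(n, seed=1, budget=100)
        anchors = ns.map_anchors(sites, small_core)
        assert sorted(anchors.anchor_indices) == sorted(small_core.surface_index)

    def test_more_sites_than_surface_rejected(self, small_core):
        sites = np.tile([0.0, 0.0, 1.0], (len(small_core.surface_index) + 1, 1))
        with pytest.raises(ValueError, match="surface beads"):
            ns.map_anchors(sites, small_core)

    def test_anchor_normals_match_core_normals(self, small_core):
        sites = optimize_virtual_sites(20, seed=5, budget=500)
        anchors = ns.map_anchors(sites, small_core)
        rows = np.searchsorted(small_core.surface_index, anchors.anchor_indices)
        assert np.allclose(anchors.normals, small_core.normals[rows])


@pytest.fixture()
def anchors40(small_core):
    sites = optimize_virtual_sites(40, seed=9, budget=2000)
    return ns.map_anchors(sites, small_core)


class TestMorphology:
    def test_homogeneous_single_label(self, anchors40):
        ns.label_morphology(anchors40, ns.MorphologySpec("homogeneous"))
        assert np.all(anchors40.labels == 1)

    def test_random_exact_counts_and_seed_reproducibility(self, anchors40):
        ns.label_morphology(anchors40, ns.MorphologySpec("random", 0.5, seed=4))
        first = anchors40.labels.copy()
        assert (first == 1).sum() == 20 and (first == 2).sum() == 20
        ns.label_morphology(anchors40, ns.MorphologySpec("random", 0.5, seed=4))
        assert np.array_equal(first, anchors40.labels)
        ns.label_morphology(anchors40, ns.MorphologySpec("random", 0.5, seed=5))
        assert not np.array_equal(first, anchors40.labels)

    @pytest.mark.parametrize("ratio, expected", [(0.25, 10), (0.5, 20), (0.9, 36)])
    def test_random_and_janus_hit_requested_ratio(self, anchors40, ratio, expected):
        for kind in ("random", "janus_z"):
            ns.label_morphology(
                anchors40, ns.MorphologySpec(kind, ratio, seed=0)
            )
            assert (anchors40.labels == 1).sum() == expected

    def test_janus_z_splits_at_the_equator(self, anchors40):
        ns.label_morphology(anchors40, ns.MorphologySpec("janus_z", 0.5))
        z = anchors40.positions[:, 2]
        assert z[anchors40.labels == 1].min() >= z[anchors40.labels == 2].max() - 1e-9

    def test_stripes_alternate_along_axis(self, anchors40):
        ns.label_morphology(
            anchors40, ns.MorphologySpec("stripe_z", n_stripes=4)
        )
        z = anchors40.positions[:, 2]
        lo, hi = z.min(), z.max()
        stripe = np.minimum(((z - lo) / ((hi - lo) / 4)).astype(int), 3)
        assert np.array_equal(anchors40.labels, 1 + stripe % 2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown morphology"):
            ns.MorphologySpec("patchy")

    def test_stripes_need_count(self):
        with pytest.raises(ValueError, match="n_stripes"):
            ns.MorphologySpec("stripe_x")


class TestBuildLigand:
    def test_two_beads_at_equilibrium_length(self, ligand3):
        fix, params = ligand3
        two = ns.LigandTemplate("L2", fix.template.beads[:2], ((0, 1),))
        built = ns.build_ligand(two, params)
        assert np.linalg.norm(
            built.coordinates[1] - built.coordinates[0]
        ) == pytest.approx(0.47, abs=1e-9)

    def test_straight_angle_gives_collinear_chain(self, ligand3):
        fix, params = ligand3
        built = ns.build_ligand(fix.template, params)
        v1 = built.coordinates[1] - built.coordinates[0]
        v2 = built.coordinates[2] - built.coordinates[1]
        cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert math.acos(np.clip(cosang, -1, 1)) < 1e-6

    def test_no_parameters_collinear_default_spacing(self, ligand3):
        fix, _ = ligand3
        built = ns.build_ligand(fix.template)
        d = np.diff(built.coordinates, axis=0)
        assert np.linalg.norm(d, axis=1) == pytest.approx(DEFAULT_SPACING)
        assert np.allclose(np.cross(d[0], d[1]), 0.0, atol=1e-9)

    def test_bent_angle_reproduced_within_tolerance(self):
        from nanosculpt.fixtures import FixtureSpec, make_ligand_fixture

        fix = make_ligand_fixture(FixtureSpec(n_beads=4, theta0=120.0))
        import nanosculpt.parameters as P

        params = P.BondedParameterSet()
        params.add_bond("C1", "C1", P.BondEntry(0.47, 1250.0))
        params.add_angle("C1", "C1", "C1", P.AngleEntry(120.0, 25.0))
        built = ns.build_ligand(fix.template, params)
        c = built.coordinates
        for i in range(1, 3):
            v1 = c[i - 1] - c[i]
            v2 = c[i + 1] - c[i]
            ang = math.degrees(
                math.acos(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            )
            assert ang == pytest.approx(120.0, abs=1e-6)
            assert np.linalg.norm(c[i + 1] - c[i]) == pytest.approx(0.47, abs=1e-9)

    def test_missing_bond_entry_noted_and_defaulted(self):
        import nanosculpt.parameters as P

        beads = tuple(
            ns.LigandBead(f"B{i}", "QX", 54.0, 0.0) for i in range(2)
        )
        built = ns.build_ligand(
            ns.LigandTemplate("Q", beads, ((0, 1),)), P.BondedParameterSet()
        )
        assert any("missing bond" in note for note in built.notes)
        assert np.linalg.norm(
            built.coordinates[1] - built.coordinates[0]
        ) == pytest.approx(DEFAULT_SPACING)


class TestGraft:
    def test_pc1_aligned_with_anchor_normal(self, grafted_model):
        model, _ = grafted_model
        for lig, anchors_row in zip(model.ligands, model.anchors.normals):
            span = lig.coordinates[-1] - lig.coordinates[0]
            cosang = span @ anchors_row / np.linalg.norm(span)
            assert math.acos(np.clip(cosang, -1, 1)) < 1e-6

    def test_grafting_is_rigid(self, grafted_model, ligand3):
        """Every grafted copy is congruent to the built template."""
        model, params = grafted_model
        fix, _ = ligand3
        template_d = pdist(ns.build_ligand(fix.template, params).coordinates)
        for lig in model.ligands:
            assert np.abs(pdist(lig.coordinates) - template_d).max() < 1e-9

    def test_attachment_offset_along_normal(self, grafted_model):
        model, params = grafted_model
        d0 = params.bond("C1", "C1").length
        for a, lig in enumerate(model.ligands):
            offset = lig.coordinates[0] - model.anchors.positions[a]
            assert np.linalg.norm(offset) == pytest.approx(d0, abs=1e-9)
            assert np.allclose(
                offset / np.linalg.norm(offset), model.anchors.normals[a], atol=1e-9
            )

    def test_kept_rotation_maximizes_min_distance(self, small_core):
        """The stored orientation beats all 20 candidate spins.

        Oracle: re-enumerate the 18-degree rotation grid for the last
        anchor of a bent two-ligand graft and score each candidate by its
        minimum distance to the rest of the system.
        """
        import nanosculpt.parameters as P
        from scipy.spatial.transform import Rotation

        params = P.BondedParameterSet()
        params.add_bond("C1", "C1", P.BondEntry(0.47, 1250.0))
        params.add_angle("C1", "C1", "C1", P.AngleEntry(120.0, 25.0))
        beads = tuple(ns.LigandBead(f"C{i}", "C1", 72.0, 0.0) for i in range(4))
        tpl = ns.LigandTemplate("BENT", beads, ((0, 1), (1, 2), (2, 3)))
        built = ns.build_ligand(tpl, params)

        sites = optimize_virtual_sites(2, seed=2, budget=500)
        anchors = ns.map_anchors(sites, small_core)
        ns.label_morphology(anchors, ns.MorphologySpec("homogeneous"))
        model = ns.graft_ligands(small_core, anchors, {1: built}, params=params)

        rest = np.concatenate([small_core.positions, model.ligands[0].coordinates])
        kept = model.ligands[1].coordinates
        normal = anchors.normals[1]
        base = kept[0]

        def min_dist(pts):
            return np.sqrt(
                ((pts[:, None, :] - rest[None, :, :]) ** 2).sum(-1)
            ).min()

        kept_score = min_dist(kept)
        for k in range(20):
            spin = Rotation.from_rotvec(normal * (2 * math.pi * k / 20))
            cand = spin.apply(kept - base) + base
            assert min_dist(cand) <= kept_score + 1e-9

    def test_anchor_bijection(self, grafted_model):
        model, _ = grafted_model
        indices = [lig.anchor_index for lig in model.ligands]
        assert len(set(indices)) == len(indices) == model.anchors.n_lig

    def test_missing_template_rejected(self, small_core, ligand3):
        fix, params = ligand3
        sites = optimize_virtual_sites(4, seed=0, budget=200)
        anchors = ns.map_anchors(sites, small_core)
        ns.label_morphology(anchors, ns.MorphologySpec("random", 0.5, seed=1))
        with pytest.raises(ValueError, match="label"):
            ns.graft_ligands(
                small_core, anchors, {1: ns.build_ligand(fix.template, params)}
            )
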