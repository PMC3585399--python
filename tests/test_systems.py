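"""Templates, anchor geometries, cage and site builders, minimisation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rlfsim import (
    anchor_geometry,
    build_abstract_system,
    build_ligand_template,
    build_site_model,
    minimise,
    toy_anchored_atom,
    total_energy,
)
from rlfsim.errors import (
    ConstructionClashError,
    FixtureNotFoundError,
    UnsupportedCoordinationError,
    UnsupportedTemplateError,
)
from rlfsim.systems import Atom, ParticleSystem, pack_points_on_sphere, _atom
from rlfsim.constants import ion_type_name


class TestLigandTemplates:
    def test_formaldehyde_charges_and_shape(self):
        t = build_ligand_template("formaldehyde_like")
        assert [a.element for a in t.atoms] == ["C", "O", "H", "H"]
        assert [a.charge for a in t.atoms] == [0.5, -0.5, 0.0, 0.0]
        assert t.net_charge == pytest.approx(0.0, abs=1e-12)
        assert t.coordinating == (1,)

    def test_carboxylate_is_bidentate_and_anionic(self):
        t = build_ligand_template("carboxylate")
        assert len(t.coordinating) == 2
        assert all(t.atoms[i].element == "O" for i in t.coordinating)
        assert t.net_charge == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("kind", ["backbone_carbonyl", "hydroxyl"])
    def test_neutral_fragments(self, kind):
        t = build_ligand_template(kind)
        assert t.net_charge == pytest.approx(0.0, abs=1e-12)
        # every bonded term references an existing atom (validate() enforces)
        t.validate()

    def test_unknown_kind_rejected(self):
        with pytest.raises(UnsupportedTemplateError):
            build_ligand_template("sulfate")


class TestAnchorGeometry:
    @pytest.mark.parametrize("n,angle", [(4, 109.4712), (6, 90.0)])
    def test_polyhedron_minimum_angles(self, n, angle):
        g = anchor_geometry(n, 2.3)
        assert g.min_pair_angle() == pytest.approx(angle, abs=1e-3)

    def test_square_antiprism_beats_cube(self):
        anti = anchor_geometry(8, 1.0)
        cube = anchor_geometry(8, 1.0, eight_fold="cube")
        assert anti.min_pair_angle() > cube.min_pair_angle()
        assert cube.min_pair_angle() == pytest.approx(70.5288, abs=1e-3)

    @pytest.mark.parametrize("n", [5, 7])
    def test_packed_points_on_sphere(self, n):
        g = anchor_geometry(n, 1.7)
        assert np.allclose(np.linalg.norm(g.points, axis=1), 1.7, atol=1e-9)
        assert g.source == "sphere_packing"

    @pytest.mark.parametrize("n,angle", [(4, 109.4712), (6, 90.0)])
    def test_packing_optimiser_recovers_polyhedra(self, n, angle):
        """The repulsion optimiser converges to the closed-form optimum."""
        pts = pack_points_on_sphere(n, seed=0, n_iter=100_000)
        u = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cosmax = max(
            float(u[i] @ u[j]) for i in range(n) for j in range(i + 1, n)
        )
        assert math.degrees(math.acos(cosmax)) == pytest.approx(angle, abs=1e-3)

    @pytest.mark.parametrize("n", [3, 9])
    def test_unsupported_coordination(self, n):
        with pytest.raises(UnsupportedCoordinationError):
            anchor_geometry(n, 2.3)

    @given(st.integers(4, 8), st.floats(0.5, 5.0))
    def test_points_lie_on_sphere(self, n, radius):
        g = anchor_geometry(n, radius)
        assert np.allclose(np.linalg.norm(g.points, axis=1), radius, atol=1e-9)


class TestAbstractCages:
    def test_unanchored_hexacoordinate_sodium(self):
        s = build_abstract_system("Na", 6, R_opt=2.3, kf=0.0)
        assert s.n_atoms == 25  # ion + 6 x 4-atom ligands
        assert np.all(s.kf == 0.0)
        assert s.total_charge == pytest.approx(1.0)
        assert s.coordinating.sum() == 6

    def test_dual_set_morph_system(self):
        s = build_abstract_system("K", 8, R_opt=2.9, kf=100.0, dual_sets=True)
        assert s.mode == "dual_restraint"
        assert np.sum(s.set_id == 0) == np.sum(s.set_id == 1) == 32
        # anchors on the first set only
        assert np.all(s.kf[s.set_id == 0] == 100.0)
        assert np.all(s.kf[s.set_id == 1] == 0.0)
        assert s.total_charge == pytest.approx(1.0)

    def test_anchors_require_radius(self):
        with pytest.raises(ValueError):
            build_abstract_system("Na", 6, kf=10.0)

    def test_construction_clash_detected(self):
        with pytest.raises(ConstructionClashError):
            build_abstract_system("Li", 4, R_opt=0.25)

    def test_deterministic_construction(self):
        a = build_abstract_system("Na", 5, R_opt=2.4, kf=10.0)
        b = build_abstract_system("Na", 5, R_opt=2.4, kf=10.0)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.anchor_pos, b.anchor_pos)


class TestSiteModels:
    def test_leut_na2_composition(self):
        m = build_site_model("LeuT_Na2", "Na", minimise_steps=300)
        assert m.n_ligands == 5
        assert sorted(m.ligand_kinds) == sorted(
            ["carbonyl", "carbonyl", "carbonyl", "hydroxyl", "hydroxyl"]
        )

    def test_glt_na1_has_bidentate_carboxylate(self):
        m = build_site_model("Glt_Na1", "Na", minimise_steps=300)
        assert "carboxylate" in m.ligand_kinds
        # 3 carbonyl O + 2 carboxylate O all feel the wall
        assert int(m.coordinating.sum()) == 5
        assert m.total_charge == pytest.approx(0.0, abs=1e-9)

    def test_leut_na1_net_neutral(self):
        m = build_site_model("LeuT_Na1", "Na", minimise_steps=300)
        assert m.n_ligands == 6
        assert m.total_charge == pytest.approx(0.0, abs=1e-9)

    def test_unknown_site_rejected(self):
        with pytest.raises(FixtureNotFoundError):
            build_site_model("KcsA_S2", "K")

    def test_smaller_ion_minimises_closer(self):
        d = {}
        for ion in ("Li", "K"):
            m = build_site_model("Glt_Na2", ion, minimise_steps=500)
            d[ion] = np.linalg.norm(m.anchor_pos[m.coordinating], axis=1).mean()
        assert d["Li"] < d["K"]


def _single_ligand_system(ion, z):
    """One formaldehyde-like ligand on the +z axis with its oxygen at z."""
    t = build_ligand_template("formaldehyde_like")
    return ParticleSystem(
        ion_species=ion,
        coords=t.coords + np.array([0.0, 0.0, z]),
        atoms=t.atoms,
        ligand_id=np.zeros(t.n_atoms, dtype=int),
        set_id=np.zeros(t.n_atoms, dtype=int),
        coordinating=np.array([i in t.coordinating for i in range(t.n_atoms)]),
        bonds=np.array([[b[0], b[1]] for b in t.bonds]),
        bond_r0=np.array([b[2] for b in t.bonds]),
        bond_k=np.array([b[3] for b in t.bonds]),
        angles=np.array([[a[0], a[1], a[2]] for a in t.angles]),
        angle_t0=np.array([a[3] for a in t.angles]),
        angle_k=np.array([a[4] for a in t.angles]),
        kf=np.zeros(t.n_atoms), kf_end=np.zeros(t.n_atoms),
        anchor_pos=t.coords + np.array([0.0, 0.0, z]),
        mode="none",
    )


class TestMinimise:
    def test_atom_at_anchor_is_stationary(self):
        toy = toy_anchored_atom(10.0)
        out = minimise(toy, max_steps=100, tol=1e-8)
        assert np.allclose(out.coords, toy.coords, atol=1e-10)

    def test_pair_minimum_matches_distance_scan(self):
        """Flexible minimisation lands where the rigid 1-D energy scan does."""
        ion = "Na"
        zs = np.arange(1.6, 3.5, 0.001)
        energies = [total_energy(_single_ligand_system(ion, z)).total for z in zs]
        z_scan = zs[int(np.argmin(energies))]
        m = minimise(_single_ligand_system(ion, 2.6), max_steps=2000, tol=1e-6)
        z_min = np.linalg.norm(m.coords[1])  # oxygen is atom 1 of the ligand
        assert z_min == pytest.approx(z_scan, abs=0.05)

    def test_smaller_ion_sits_closer(self):
        out = {}
        for ion in ("Li", "K"):
            m = minimise(_single_ligand_system(ion, 2.6), max_steps=2000, tol=1e-6)
            out[ion] = np.linalg.norm(m.coords[1])
        assert out["Li"] < out["K"]


class TestInvariants:
    @pytest.mark.parametrize("ion,n", [("Li", 4), ("Na", 6), ("K", 8)])
    def test_charge_conservation(self, ion, n):
        s = build_abstract_system(ion, n, R_opt=2.6)
        ion_q = _atom(ion_type_name(ion)).charge
        assert s.total_charge == pytest.approx(
            ion_q + sum(a.charge for a in s.atoms), abs=1e-12
        )
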