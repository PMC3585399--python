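"""Pair energetics, switching, softcore, restraints, forces."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rlfsim import (
    NonbondedParams,
    build_abstract_system,
    forces,
    pair_energy,
    restraint_energy,
    total_energy,
)
from rlfsim.energetics import _energy_forces
from rlfsim.systems import RestraintSpec, make_restraint_morph_system

from conftest import make_bare_ion


class TestPairEnergy:
    def test_lj_minimum_depth(self):
        eps, sig = 0.15, 3.0
        r = 2.0 ** (1.0 / 6.0) * sig
        assert pair_energy(0, 0, eps, sig, r) == pytest.approx(-eps, rel=1e-12)

    def test_zero_beyond_cutoff(self):
        assert pair_energy(1.0, -0.5, 0.1, 3.0, 12.0) == 0.0
        assert pair_energy(1.0, -0.5, 0.1, 3.0, 15.0) == 0.0

    def test_coulomb_value(self):
        # +1 x -0.5 at 3 A: kcal*A/(mol*e^2) constant cross-checked against an
        # independent unit conversion (e^2/(4 pi eps0) = 332.064 kcal*A/mol)
        u = pair_energy(1.0, -0.5, 0.0, 1.0, 3.0)
        assert u == pytest.approx(-55.34395, abs=1e-4)

    def test_continuity_at_switch_and_cutoff(self):
        eps = 1e-9  # jump beyond the smooth slope must vanish
        for r0 in (10.0, 12.0):
            lo = pair_energy(0.5, -0.5, 0.2, 3.2, r0 - eps)
            hi = pair_energy(0.5, -0.5, 0.2, 3.2, r0 + eps)
            assert abs(hi - lo) < 1e-8

    def test_softcore_finite_at_contact(self):
        u = pair_energy(1.0, -0.76, 0.1, 2.7, 1e-6, lam_vdw=0.5, lam_elec=0.5)
        assert np.isfinite(u)

    def test_singularity_raises_when_fully_coupled(self):
        with pytest.raises(ZeroDivisionError):
            pair_energy(1.0, -0.5, 0.1, 3.0, 0.0)

    @given(st.floats(0.5, 9.5), st.floats(0.01, 0.3), st.floats(1.0, 4.0))
    def test_softcore_endpoint_equals_plain_lj(self, r, eps, sig):
        plain = 4 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
        assert pair_energy(0, 0, eps, sig, r, lam_vdw=1.0) == pytest.approx(
            plain, rel=1e-10, abs=1e-12
        )

    def test_switch_params_validated(self):
        with pytest.raises(ValueError):
            NonbondedParams(cutoff=10.0, switch_start=12.0)


class TestRestraintEnergy:
    def test_inside_wall_is_free(self):
        spec = RestraintSpec()
        e = restraint_energy(np.array([0.0, 0.0, 3.4]), spec)
        assert e.wall_restraint == 0.0

    def test_wall_is_half_k_quadratic(self):
        spec = RestraintSpec(k_wall=100.0)
        e = restraint_energy(np.array([0.0, 0.0, 3.6]), spec)
        assert e.wall_restraint == pytest.approx(0.5, abs=1e-9)

    def test_atom_at_anchor_costs_nothing(self):
        spec = RestraintSpec(kf=250.0, anchor_position=np.array([1.0, 2.0, 0.5]))
        e = restraint_energy(np.array([1.0, 2.0, 0.5]), spec)
        assert e.anchor_restraint == 0.0

    def test_kf_zero_needs_no_anchor_and_negative_rejected(self):
        RestraintSpec(kf=0.0)
        with pytest.raises(ValueError):
            RestraintSpec(kf=-1.0)


class TestTotalEnergy:
    def test_isolated_ion_is_zero(self):
        assert total_energy(make_bare_ion()).total == 0.0

    def test_breakdown_sums_to_total(self, na6_cage):
        e = total_energy(na6_cage)
        s = e.coulomb + e.lj + e.bonded + e.wall_restraint + e.anchor_restraint
        assert e.total == pytest.approx(s, abs=1e-9)

    def test_translation_invariance(self, na6_cage):
        packed = na6_cage.packed()
        args = packed.static_args()
        c0, _ = _energy_forces(packed.pos, 0.0, *args)
        shifted = packed.pos + np.array([1.7, -0.4, 2.2])
        c1, _ = _energy_forces(shifted, 0.0, *args)
        # wall is centred on the ion, which moved too; no anchors at kf=0
        assert np.allclose(c0, c1, atol=1e-9)

    def test_rotation_invariance_of_wall(self, na6_cage):
        packed = na6_cage.packed()
        args = packed.static_args()
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        c0, _ = _energy_forces(packed.pos, 0.0, *args)
        c1, _ = _energy_forces(packed.pos @ rot.T, 0.0, *args)
        assert np.allclose(c0, c1, atol=1e-9)

    def test_dual_sets_do_not_interact(self):
        base = build_abstract_system("Na", 5, R_opt=2.4, kf=50.0)
        dual = make_restraint_morph_system(
            build_abstract_system("Na", 5, R_opt=2.4), 50.0
        )
        e_base = total_energy(base)
        e_dual = total_energy(dual, 0.0)
        # the decoupled free set adds only its (identical) bonded terms
        assert e_dual.coulomb == pytest.approx(e_base.coulomb, abs=1e-9)
        assert e_dual.lj == pytest.approx(e_base.lj, abs=1e-9)
        assert e_dual.bonded == pytest.approx(2 * e_base.bonded, abs=1e-9)
        assert e_dual.anchor_restraint == pytest.approx(
            e_base.anchor_restraint, abs=1e-9
        )


class TestForces:
    def test_matches_finite_differences(self, na6_cage, rng):
        packed = na6_cage.packed()
        args = packed.static_args()
        pos = packed.pos + 0.08 * rng.standard_normal(packed.pos.shape)
        for lam in (0.0, 0.37):
            _, f = _energy_forces(pos, lam, *args)
            h = 1e-6
            for i in (1, 7, 13, 24):
                for d in range(3):
                    pp = pos.copy(); pp[i, d] += h
                    pm = pos.copy(); pm[i, d] -= h
                    cp, _ = _energy_forces(pp, lam, *args)
                    cm, _ = _energy_forces(pm, lam, *args)
                    num = -(cp.sum() - cm.sum()) / (2 * h)
                    assert f[i, d] == pytest.approx(num, rel=1e-5, abs=1e-6)

    def test_mirror_symmetric_forces(self):
        s = build_abstract_system("Na", 6, R_opt=2.4)
        packed = s.packed()
        args = packed.static_args()
        mirror = packed.pos.copy()
        mirror[:, 2] *= -1.0
        c0, f0 = _energy_forces(packed.pos, 0.0, *args)
        c1, f1 = _energy_forces(mirror, 0.0, *args)
        # the octahedral cage maps onto itself under z-reflection up to an
        # atom permutation: energies match exactly, force magnitudes match
        # as multisets
        assert np.allclose(c0, c1, atol=1e-9)
        assert np.allclose(
            np.sort(np.linalg.norm(f0, axis=1)),
            np.sort(np.linalg.norm(f1, axis=1)),
            atol=1e-9,
        )

    def test_anchored_atom_at_anchor_feels_nothing(self):
        from rlfsim import toy_anchored_atom

        f = forces(toy_anchored_atom(100.0))
        assert np.allclose(f, 0.0, atol=1e-12)
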