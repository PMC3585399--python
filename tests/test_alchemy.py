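"""Free-energy estimators, morph legs, cycle assembly, hysteresis."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from rlfsim import (
    KB,
    LambdaSchedule,
    anchor_geometry,
    assemble_cycle,
    estimate_bar,
    estimate_exp,
    hysteresis,
    hysteresis_summary,
    run_ion_morph,
    run_kf_morph,
    run_restraint_morph,
    toy_ideal_gas,
)
from rlfsim.alchemy import FEPLegResult, _zero_leg
from rlfsim.errors import (
    CycleInconsistencyError,
    InsufficientSamplingError,
    ProtocolError,
    StrainContaminationError,
)

from conftest import make_bare_ion

KT = KB * 310.0


def _leg(kind, ions, n, kf, windows, direction="forward", u0=0.0, u1=0.0):
    return FEPLegResult(
        leg_kind=kind, ions=ions, n=n, kf=kf,
        per_window_dG=np.asarray(windows, dtype=float),
        per_window_se=np.zeros(len(windows)),
        direction=direction, seed=0, samples_per_window=100,
        u_end_first=u0, u_end_last=u1,
    )


class TestLambdaSchedule:
    def test_defaults_are_valid_and_dense_at_endpoints(self):
        s = LambdaSchedule.restraint_default()
        assert s.values[0] == 0.0 and s.values[-1] == 1.0
        assert s.values[1] < 1e-4 and s.values[-2] > 0.9999
        assert LambdaSchedule.ion_default().n_windows == 21

    def test_reverse_is_exact_mirror(self):
        s = LambdaSchedule.restraint_default()
        r = s.reversed()
        assert r.values == tuple(reversed(s.values))
        assert r.reversed().values == s.values

    @pytest.mark.parametrize("values", [(0.0, 0.5, 0.5, 1.0), (0.1, 0.5, 1.0),
                                        (0.0, 0.7, 0.3, 1.0)])
    def test_malformed_schedules_rejected(self, values):
        with pytest.raises(ValueError):
            LambdaSchedule(values)


class TestExpEstimator:
    def test_identical_hamiltonians_give_zero(self):
        windows = [np.zeros(50) for _ in range(4)]
        res = estimate_exp(windows)
        assert res.total_dG == 0.0

    def test_constant_shift_recovered_exactly(self):
        windows = [np.full(50, 0.7), np.full(50, -0.2)]
        res = estimate_exp(windows)
        assert np.allclose(res.per_window_dG, [0.7, -0.2], atol=1e-12)
        assert res.total_dG == pytest.approx(0.5, abs=1e-12)

    def test_insufficient_sampling_rejected(self):
        with pytest.raises(InsufficientSamplingError):
            estimate_exp([np.zeros(5)])


class TestBarEstimator:
    def test_symmetric_toy_gives_zero(self, rng):
        w = rng.normal(1.0, 0.5, size=400)
        res = estimate_bar([w], [w.copy()])
        assert res.total_dG == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_work_distributions(self, rng):
        """Crooks-consistent Gaussian work: both estimators find the true dF
        and agree within combined errors."""
        df_true, spread = 1.2, 0.8
        wf = rng.normal(df_true + spread, math.sqrt(2 * spread * KT), 4000)
        wr = rng.normal(-df_true + spread, math.sqrt(2 * spread * KT), 4000)
        bar = estimate_bar([wf], [wr])
        exp = estimate_exp([wf])
        assert bar.total_dG == pytest.approx(df_true, abs=3 * max(bar.se, 0.02))
        assert abs(bar.total_dG - exp.total_dG) <= 2 * math.hypot(bar.se, exp.se) + 0.05

    def test_mismatched_tables_rejected(self):
        with pytest.raises(ValueError):
            estimate_bar([np.zeros(20)], [np.zeros(20), np.zeros(20)])


class TestConfinementOracle:
    def test_ideal_gas_matches_configuration_integral(self):
        """Four non-interacting walled atoms morphing into kf=25 anchors:
        free energy and endpoint mean energies are 4x radial quadratures,
        and the confinement is overwhelmingly entropic (|dH| << dG)."""
        kf, k_wall, rw = 25.0, 100.0, 3.5

        def u_of(r, lam):
            u = 0.5 * lam * kf * r**2
            if r > rw:
                u += 0.5 * k_wall * (r - rw) ** 2
            return u

        def boltz(r, lam):
            return 4.0 * math.pi * r**2 * math.exp(-u_of(r, lam) / KT)

        def z_and_u(lam):
            z = quad(lambda r: boltz(r, lam), 0, 8.0, limit=200)[0]
            zu = quad(lambda r: u_of(r, lam) * boltz(r, lam), 0, 8.0,
                      limit=200)[0]
            return z, zu / z

        z0, u0 = z_and_u(0.0)
        z1, u1 = z_and_u(1.0)  # u1 ~ (3/2) kT by equipartition
        exact_dG = -4.0 * KT * math.log(z1 / z0)
        exact_dH = 4.0 * (u1 - u0)

        gas = toy_ideal_gas(4, kf=0.0)
        # geometric lambda ladder: switching on a confinement from zero needs
        # dense spacing where the accessible volume shrinks fastest
        sched = LambdaSchedule((0.0, 0.002, 0.004, 0.008, 0.016, 0.03, 0.06,
                                0.12, 0.25, 0.5, 1.0))
        leg = run_kf_morph(gas, 0.0, kf, schedule=sched, seed=11,
                           nsteps_per_window=60_000)
        assert leg.total_dG == pytest.approx(exact_dG, abs=max(2 * leg.se, 0.08))
        assert leg.dH == pytest.approx(exact_dH, abs=0.3)
        # -T dS carries essentially all of the confinement free energy
        assert (leg.total_dG - leg.dH) / leg.total_dG > 0.75


class TestMorphLegs:
    def test_zero_stiffness_morph_is_identically_zero(self):
        anchors = anchor_geometry(5, 2.4, ion="Na")
        leg = run_restraint_morph("Na", 5, 0.0, anchors, seed=0)
        assert leg.total_dG == 0.0 and leg.se == 0.0

    def test_strain_contamination_refused(self):
        anchors = anchor_geometry(5, 2.67, ion="K")
        with pytest.raises(StrainContaminationError):
            run_restraint_morph("Na", 5, 10.0, anchors, seed=0)
        # the strained-cavity protocol must be an explicit, flagged mode
        leg = run_restraint_morph("Na", 5, 0.0, anchors, seed=0,
                                  allow_strain=True)
        assert leg.total_dG == 0.0

    def test_ion_morph_refuses_anchored_system(self):
        from rlfsim import build_abstract_system

        anchored = build_abstract_system("Na", 5, R_opt=2.4, kf=10.0)
        with pytest.raises(ProtocolError):
            run_ion_morph(5, "Na", "K", system=anchored,
                          nsteps_per_window=1000)

    def test_identity_ion_morph_is_zero(self):
        leg = run_ion_morph(4, "Na", "Na", seed=9, nsteps_per_window=2_000,
                            R_start=2.3)
        assert leg.total_dG == pytest.approx(0.0, abs=1e-9)

    def test_ion_morph_in_empty_system_is_zero(self):
        from rlfsim import make_ion_morph_system
        from rlfsim.alchemy import run_leg

        morph = make_ion_morph_system(make_bare_ion("Na"), "K")
        leg = run_leg(morph, LambdaSchedule.ion_default(), 2_000, seed=0,
                      leg_kind="ion_morph", ions=("Na", "K"), n=0, kf=0.0)
        assert leg.total_dG == pytest.approx(0.0, abs=1e-9)


class TestCycleAssembly:
    def test_null_cycle(self):
        sched = LambdaSchedule.restraint_default()
        a = _zero_leg("restraint_morph", ("Na",), 5, 0.0, sched, 0)
        b = _zero_leg("restraint_morph", ("K",), 5, 0.0, sched, 0)
        x = _leg("ion_morph", ("Na", "K"), 5, 0.0, [0.0])
        cyc = assemble_cycle(a, b, x, ddG_hydr=0.0)
        assert cyc.ddG_exchange == 0.0
        assert cyc.ddG_RLF == 0.0

    def test_signed_sum_convention(self):
        a = _leg("restraint_morph", ("Na",), 5, 10.0, [1.0])
        b = _leg("restraint_morph", ("K",), 5, 10.0, [-2.0])
        x = _leg("ion_morph", ("Na", "K"), 5, 0.0, [0.5])
        cyc = assemble_cycle(a, b, x, ddG_hydr=3.0)
        # ddG = dG_c,B - dG_c,A - dG_site + ddG_hydr = -2 - 1 - 0.5 + 3
        assert cyc.ddG_exchange == pytest.approx(-0.5, abs=1e-12)

    def test_mismatched_legs_rejected(self):
        a = _leg("restraint_morph", ("Na",), 5, 10.0, [1.0])
        b6 = _leg("restraint_morph", ("K",), 6, 10.0, [1.0])
        x = _leg("ion_morph", ("Na", "K"), 5, 0.0, [0.5])
        with pytest.raises(CycleInconsistencyError):
            assemble_cycle(a, b6, x)
        b_wrong_ion = _leg("restraint_morph", ("Li",), 5, 10.0, [1.0])
        with pytest.raises(CycleInconsistencyError):
            assemble_cycle(a, b_wrong_ion, x)


class TestHysteresis:
    def test_perfectly_reversed_legs_have_none(self):
        fw = _leg("kf_morph", ("Na",), 1, 10.0, [1.0, 0.5])
        rv = _leg("kf_morph", ("Na",), 1, 10.0, [-0.5, -1.0],
                  direction="reverse")
        assert hysteresis(fw, rv) == 0.0
        assert hysteresis_summary([(fw, rv)]) == (0.0, 0.0)

    def test_same_direction_rejected(self):
        fw = _leg("kf_morph", ("Na",), 1, 10.0, [1.0])
        with pytest.raises(ValueError):
            hysteresis(fw, fw)
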