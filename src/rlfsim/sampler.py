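"""Canonical-ensemble Langevin dynamics of particle systems.

BAOAB-discretised Langevin integration at the target temperature (default
310 K, 1 fs timestep, friction 5 ps^-1).  The central ion never moves.  The
integrator lives in a single numba loop that also re-evaluates the potential
at any requested alchemical lambda values at every save point, which is what
free-energy perturbation consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .constants import ACC_CONV, DT_DEFAULT, FRICTION_DEFAULT, KB
from .energetics import EnergyBreakdown, PackedSystem, _energy_forces
from .errors import InstabilityError

_EMAX = 1.0e6  # kcal/mol; beyond this the run is declared unstable


@njit(cache=True, fastmath=True)
def _baoab(
    pos0, vel0, lam, lam_evals, nsteps, save_interval, seed,
    dt, gamma, kT, mass, mobile,
    pair_i, pair_j, pair_qq, pair_eps, pair_sig2, pair_wea, pair_web,
    pair_wva, pair_wvb, pair_soft, wall,
    kf_a, kf_b, anchor,
    bond_i, bond_j, bond_r0, bond_k,
    ang_i, ang_j, ang_k, ang_t0, ang_kt,
    r_on, r_off, sc_shift, k_wall, r_wall,
):
    np.random.seed(seed)
    n = pos0.shape[0]
    pos = pos0.copy()
    vel = vel0.copy()
    n_frames = nsteps // save_interval + 1
    n_ev = lam_evals.shape[0]
    frames = np.empty((n_frames, n, 3))
    comps_out = np.empty((n_frames, 5))
    cross = np.empty((n_frames, n_ev))
    kinetic = np.empty(n_frames)

    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    sig_v = np.empty(n)
    inv_m = np.empty(n)
    for i in range(n):
        sig_v[i] = math.sqrt(kT * ACC_CONV / mass[i]) if kT > 0.0 else 0.0
        inv_m[i] = ACC_CONV / mass[i]

    comps, f = _energy_forces(
        pos, lam, pair_i, pair_j, pair_qq, pair_eps, pair_sig2, pair_wea,
        pair_web, pair_wva, pair_wvb, pair_soft, wall, kf_a, kf_b, anchor,
        bond_i, bond_j, bond_r0, bond_k, ang_i, ang_j, ang_k, ang_t0, ang_kt,
        r_on, r_off, sc_shift, k_wall, r_wall,
    )

    frame = 0
    # initial frame
    frames[frame] = pos
    comps_out[frame] = comps
    ke = 0.0
    for i in range(n):
        if mobile[i]:
            ke += 0.5 * mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    kinetic[frame] = ke / ACC_CONV
    for e in range(n_ev):
        ce, _ = _energy_forces(
            pos, lam_evals[e], pair_i, pair_j, pair_qq, pair_eps, pair_sig2,
            pair_wea, pair_web, pair_wva, pair_wvb, pair_soft, wall, kf_a, kf_b, anchor,
            bond_i, bond_j, bond_r0, bond_k, ang_i, ang_j, ang_k, ang_t0,
            ang_kt, r_on, r_off, sc_shift, k_wall, r_wall,
        )
        cross[frame, e] = ce[0] + ce[1] + ce[2] + ce[3] + ce[4]
    frame += 1

    half = 0.5 * dt
    for step in range(1, nsteps + 1):
        noise = np.random.standard_normal(3 * n)
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += half * f[i, 0] * inv_m[i]
                vel[i, 1] += half * f[i, 1] * inv_m[i]
                vel[i, 2] += half * f[i, 2] * inv_m[i]
                pos[i, 0] += half * vel[i, 0]
                pos[i, 1] += half * vel[i, 1]
                pos[i, 2] += half * vel[i, 2]
                vel[i, 0] = c1 * vel[i, 0] + c2 * sig_v[i] * noise[3 * i]
                vel[i, 1] = c1 * vel[i, 1] + c2 * sig_v[i] * noise[3 * i + 1]
                vel[i, 2] = c1 * vel[i, 2] + c2 * sig_v[i] * noise[3 * i + 2]
                pos[i, 0] += half * vel[i, 0]
                pos[i, 1] += half * vel[i, 1]
                pos[i, 2] += half * vel[i, 2]
        comps, f = _energy_forces(
            pos, lam, pair_i, pair_j, pair_qq, pair_eps, pair_sig2, pair_wea,
            pair_web, pair_wva, pair_wvb, pair_soft, wall, kf_a, kf_b, anchor,
            bond_i, bond_j, bond_r0, bond_k, ang_i, ang_j, ang_k, ang_t0,
            ang_kt, r_on, r_off, sc_shift, k_wall, r_wall,
        )
        for i in range(n):
            if mobile[i]:
                vel[i, 0] += half * f[i, 0] * inv_m[i]
                vel[i, 1] += half * f[i, 1] * inv_m[i]
                vel[i, 2] += half * f[i, 2] * inv_m[i]
        e_tot = comps[0] + comps[1] + comps[2] + comps[3] + comps[4]
        if not np.isfinite(e_tot) or abs(e_tot) > _EMAX:
            return frames[:frame], comps_out[:frame], cross[:frame], kinetic[:frame], pos, vel, step
        if step % save_interval == 0:
            frames[frame] = pos
            comps_out[frame] = comps
            ke = 0.0
            for i in range(n):
                if mobile[i]:
                    ke += 0.5 * mass[i] * (
                        vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
                    )
            kinetic[frame] = ke / ACC_CONV
            for e in range(n_ev):
                ce, _ = _energy_forces(
                    pos, lam_evals[e], pair_i, pair_j, pair_qq, pair_eps,
                    pair_sig2, pair_wea, pair_web, pair_wva, pair_wvb, pair_soft, wall,
                    kf_a, kf_b, anchor, bond_i, bond_j, bond_r0, bond_k,
                    ang_i, ang_j, ang_k, ang_t0, ang_kt,
                    r_on, r_off, sc_shift, k_wall, r_wall,
                )
                cross[frame, e] = ce[0] + ce[1] + ce[2] + ce[3] + ce[4]
            frame += 1
    return frames, comps_out, cross, kinetic, pos, vel, -1


@dataclass
class Trajectory:
    """Saved frames and energy series of one dynamics run."""

    frames: np.ndarray            # (n_frames, n_atoms, 3)
    times: np.ndarray             # fs
    components: np.ndarray        # (n_frames, 5): coulomb, lj, bonded, wall, anchor
    kinetic: np.ndarray           # kcal/mol
    cross: np.ndarray             # (n_frames, n_lam_evals)
    lam: float
    lam_evals: tuple[float, ...]
    seed: int
    temperature: float
    timestep: float
    packed: PackedSystem = field(repr=False, default=None)
    final_pos: np.ndarray = field(repr=False, default=None)
    final_vel: np.ndarray = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def potential(self) -> np.ndarray:
        return self.components.sum(axis=1)

    @property
    def n_mobile(self) -> int:
        return int(np.sum(self.packed.mobile))

    def kinetic_temperature(self) -> np.ndarray:
        """Instantaneous kinetic temperature of the mobile atoms, K."""
        return 2.0 * self.kinetic / (3.0 * self.n_mobile * KB)

    def energy_frame(self) -> pd.DataFrame:
        cols = ["coulomb", "lj", "bonded", "wall_restraint", "anchor_restraint"]
        df = pd.DataFrame(self.components, columns=cols)
        df.insert(0, "time_fs", self.times)
        df.insert(1, "lambda", self.lam)
        df["total"] = self.components.sum(axis=1)
        df["kinetic"] = self.kinetic
        return df

    def cross_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cross, columns=[f"{l:g}" for l in self.lam_evals],
                            index=self.times)

    def breakdown(self, frame: int = -1) -> EnergyBreakdown:
        return EnergyBreakdown.from_array(self.components[frame])


def _init_velocities(packed: PackedSystem, T: float, rng: np.random.Generator) -> np.ndarray:
    v = np.zeros_like(packed.pos)
    if T > 0:
        std = np.sqrt(KB * T * ACC_CONV / packed.mass)
        v = rng.standard_normal(packed.pos.shape) * std[:, None]
    v[~packed.mobile] = 0.0
    return v


def run_dynamics(
    system,
    nsteps: int,
    seed: int,
    save_interval: int = 100,
    *,
    lam: float = 0.0,
    lam_evals: tuple[float, ...] = (),
    temperature: float | None = None,
    timestep: float = DT_DEFAULT,
    friction: float = FRICTION_DEFAULT,
    pos0: np.ndarray | None = None,
    vel0: np.ndarray | None = None,
) -> Trajectory:
    """Run BAOAB Langevin dynamics and return the saved trajectory.

    Identical ``seed`` (with identical inputs) gives bit-identical
    trajectories.  Raises :class:`InstabilityError` naming the step if the
    potential energy diverges.
    """
    if nsteps < 1:
        raise ValueError("nsteps must be >= 1")
    packed = system.packed() if hasattr(system, "packed") else system
    T = packed.temperature if temperature is None else float(temperature)
    rng = np.random.default_rng(seed)
    p0 = packed.pos.copy() if pos0 is None else np.array(pos0, dtype=float)
    v0 = _init_velocities(packed, T, rng) if vel0 is None else np.array(vel0, dtype=float)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    out = _baoab(
        p0, v0, float(lam), np.asarray(lam_evals, dtype=float),
        int(nsteps), int(save_interval), kernel_seed,
        float(timestep), float(friction), KB * T,
        packed.mass, packed.mobile,
        *packed.static_args(),
    )
    frames, comps, cross, kinetic, pos, vel, bad_step = out
    if bad_step >= 0:
        raise InstabilityError(bad_step, float(comps[-1].sum()) if len(comps) else float("nan"))
    times = np.arange(frames.shape[0]) * save_interval * timestep
    return Trajectory(
        frames=frames, times=times, components=comps, kinetic=kinetic,
        cross=cross, lam=float(lam), lam_evals=tuple(float(l) for l in lam_evals),
        seed=int(seed), temperature=T, timestep=float(timestep),
        packed=packed, final_pos=pos, final_vel=vel,
    )


def sample_cross_energies(traj: Trajectory, lam_evals) -> pd.DataFrame:
    """Re-evaluate the total potential of every saved frame at each lambda.

    No dynamics are re-run; rows are frames, columns the requested lambda
    values.
    """
    lam_evals = [float(l) for l in lam_evals]
    for l in lam_evals:
        if not 0.0 <= l <= 1.0:
            raise ValueError(f"lambda {l} outside [0, 1]")
    packed = traj.packed
    args = packed.static_args()
    out = np.empty((traj.n_frames, len(lam_evals)))
    for fi in range(traj.n_frames):
        pos = traj.frames[fi]
        for li, l in enumerate(lam_evals):
            comps, _ = _energy_forces(pos, l, *args)
            out[fi, li] = comps.sum()
    return pd.DataFrame(out, columns=[f"{l:g}" for l in lam_evals], index=traj.times)
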