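"""Potential energy and analytic forces, including alchemical (lambda) states.

The Hamiltonian contains:

* switched Coulomb and 12-6 Lennard-Jones nonbonded terms (CHARMM-style
  polynomial switching between ``switch_start`` and ``cutoff``, applied to
  both terms),
* softcore Lennard-Jones for partially coupled groups
  (``r^2 -> r^2 + shift*(1-lambda)*sigma^2``),
* harmonic bonds and angles (``1/2 k (x-x0)^2`` convention throughout),
* a one-sided flat-bottom spherical wall on coordinating oxygens centred on
  the (fixed) ion,
* per-atom harmonic anchor restraints with force constant ``kf``.

Alchemical coupling uses group indices: group 0 is the environment (ion plus
any permanently coupled atoms), group 1 is the outgoing set (coupling
``1 - lambda``), group 2 is the incoming set (coupling ``lambda``).  Pairs
between groups 1 and 2 never interact (dual-topology exclusion).  An ion
identity morph instead interpolates linearly between the two ions' full
12-6 interactions at constant charge (a hard core persists at every
lambda, so no softcore is needed there).

All heavy lifting happens in a single numba kernel, `_energy_forces`, that
evaluates every term and its analytic gradient in one pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .constants import COULOMB, K_WALL_DEFAULT, WALL_RADIUS
from .errors import ParameterisationError


@dataclass(frozen=True)
class NonbondedParams:
    """Cutoff scheme and softcore settings for nonbonded interactions."""

    cutoff: float = 12.0
    switch_start: float = 10.0
    softcore_shift: float = 1.0
    coulomb_constant: float = COULOMB

    def __post_init__(self):
        if not self.switch_start < self.cutoff:
            raise ValueError(
                f"switch_start ({self.switch_start}) must be < cutoff ({self.cutoff})"
            )


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term potential energy, kcal/mol. ``total`` is the exact sum."""

    coulomb: float
    lj: float
    bonded: float
    wall_restraint: float
    anchor_restraint: float

    @property
    def total(self) -> float:
        return (
            self.coulomb
            + self.lj
            + self.bonded
            + self.wall_restraint
            + self.anchor_restraint
        )

    @classmethod
    def from_array(cls, comps: np.ndarray) -> "EnergyBreakdown":
        return cls(*(float(c) for c in comps))


@dataclass
class PackedSystem:
    """Flat-array view of a particle system ready for the numba kernel.

    Atom 0 is always the (fixed) central ion.  ``eps_b``/``sig_b`` differ from
    ``eps_a``/``sig_a`` only on the ion and only when ``morph_ion`` is set;
    ``kf_a``/``kf_b`` differ only in a force-constant interpolation morph.
    """

    pos: np.ndarray          # (N,3) float64, Angstrom
    charge: np.ndarray       # (N,)
    eps_a: np.ndarray        # (N,)
    sig_a: np.ndarray        # (N,)
    eps_b: np.ndarray
    sig_b: np.ndarray
    group: np.ndarray        # (N,) int64 in {0,1,2}
    ligand_id: np.ndarray    # (N,) int64; -1 for the ion
    wall: np.ndarray         # (N,) bool: subject to the spherical wall
    kf_a: np.ndarray         # (N,) anchor force constants at lambda=0
    kf_b: np.ndarray         # (N,) anchor force constants at lambda=1
    anchor: np.ndarray       # (N,3) anchor positions
    mass: np.ndarray         # (N,) amu
    mobile: np.ndarray       # (N,) bool; ion is immobile
    bond_i: np.ndarray       # int64 arrays; may be empty
    bond_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    ang_t0: np.ndarray       # radians
    ang_kt: np.ndarray
    morph_ion: bool = False
    k_wall: float = K_WALL_DEFAULT
    wall_radius: float = WALL_RADIUS
    temperature: float = 310.0
    nb: NonbondedParams = field(default_factory=NonbondedParams)

    @property
    def n_atoms(self) -> int:
        return self.pos.shape[0]

    def _pair_list(self) -> tuple:
        """Static nonbonded pair list with precombined parameters.

        Electrostatic and van der Waals couplings are linear in lambda,
        ``w = wa + wb*lambda`` per pair, which makes the inner loop
        branch-free: environment pairs have w = 1, the outgoing set
        1 - lambda, the incoming set lambda.  An ion-morph pair becomes two
        entries (outgoing LJ at 1 - lambda carrying the electrostatics at
        full strength, incoming LJ at lambda with no charge).
        """
        n = self.n_atoms
        pi, pj, qq, eps, sig2 = [], [], [], [], []
        wea, web, wva, wvb, soft = [], [], [], [], []

        def _entry(i, j, q, e, s, ea, eb, va, vb, sc=1.0):
            pi.append(i); pj.append(j); qq.append(q); eps.append(e)
            sig2.append(s * s)
            wea.append(ea); web.append(eb); wva.append(va); wvb.append(vb)
            soft.append(sc)

        for i in range(n - 1):
            for j in range(i + 1, n):
                if self.ligand_id[i] == self.ligand_id[j] and self.ligand_id[i] >= 0:
                    continue  # intra-ligand exclusion (1-2/1-3 covers these fragments)
                gi, gj = self.group[i], self.group[j]
                if (gi == 1 and gj == 2) or (gi == 2 and gj == 1):
                    continue  # dual-topology sets never interact
                q = self.nb.coulomb_constant * self.charge[i] * self.charge[j]
                e_a = math.sqrt(self.eps_a[i] * self.eps_a[j])
                s_a = 0.5 * (self.sig_a[i] + self.sig_a[j])
                e_b = math.sqrt(self.eps_b[i] * self.eps_b[j])
                if q == 0.0 and e_a == 0.0 and e_b == 0.0:
                    continue  # non-interacting pair (oracle toys); also avoids r=0
                if self.morph_ion and (i == 0 or j == 0):
                    # linear interpolation of the two ions' full 12-6 terms:
                    # a hard core persists at every lambda, so no softcore
                    s_b = 0.5 * (self.sig_b[i] + self.sig_b[j])
                    _entry(i, j, q, e_a, s_a, 1.0, 0.0, 1.0, -1.0, sc=0.0)
                    _entry(i, j, 0.0, e_b, s_b, 0.0, 0.0, 0.0, 1.0, sc=0.0)
                elif gi == 1 or gj == 1:
                    _entry(i, j, q, e_a, s_a, 1.0, -1.0, 1.0, -1.0)
                elif gi == 2 or gj == 2:
                    _entry(i, j, q, e_a, s_a, 0.0, 1.0, 0.0, 1.0)
                else:
                    _entry(i, j, q, e_a, s_a, 1.0, 0.0, 1.0, 0.0)
        return (
            np.asarray(pi, dtype=np.int64), np.asarray(pj, dtype=np.int64),
            np.asarray(qq, dtype=np.float64), np.asarray(eps, dtype=np.float64),
            np.asarray(sig2, dtype=np.float64),
            np.asarray(wea, dtype=np.float64), np.asarray(web, dtype=np.float64),
            np.asarray(wva, dtype=np.float64), np.asarray(wvb, dtype=np.float64),
            np.asarray(soft, dtype=np.float64),
        )

    def static_args(self) -> tuple:
        """Everything the kernel needs besides positions and lambda."""
        if not hasattr(self, "_static"):
            self._static = self._pair_list() + (
                self.wall.astype(np.uint8),
                self.kf_a, self.kf_b, self.anchor,
                self.bond_i, self.bond_j, self.bond_r0, self.bond_k,
                self.ang_i, self.ang_j, self.ang_k, self.ang_t0, self.ang_kt,
                self.nb.switch_start, self.nb.cutoff, self.nb.softcore_shift,
                self.k_wall, self.wall_radius,
            )
        return self._static

    def validate(self):
        n = self.n_atoms
        for name in ("charge", "eps_a", "sig_a", "eps_b", "sig_b", "mass"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ParameterisationError(f"array {name} has wrong shape")
            if not np.all(np.isfinite(arr)):
                raise ParameterisationError(f"non-finite values in {name}")
        if np.any(self.eps_a < 0) or np.any(self.eps_b < 0):
            raise ParameterisationError("negative Lennard-Jones epsilon")
        if np.any(self.kf_a < 0) or np.any(self.kf_b < 0):
            raise ParameterisationError("negative anchor force constant")
        if self.mobile[0]:
            raise ParameterisationError("ion (atom 0) must be immobile")


@njit(cache=True, fastmath=True)
def _switch(r2, ron2, roff2):
    """CHARMM switching function S(r^2) and dS/d(r^2)."""
    if r2 <= ron2:
        return 1.0, 0.0
    if r2 >= roff2:
        return 0.0, 0.0
    denom = (roff2 - ron2) ** 3
    a = roff2 - r2
    s = a * a * (roff2 + 2.0 * r2 - 3.0 * ron2) / denom
    ds = 6.0 * a * (ron2 - r2) / denom
    return s, ds


@njit(cache=True, fastmath=True)
def _lj_soft(eps, sig, r2, c, shift):
    """Softcore 12-6 term c*4*eps*(s^12 - s^6) with r^2 -> r^2 + shift*(1-c)*sig^2.

    Returns (u, du/dr2). ``c`` is both the linear coupling prefactor and the
    softcore progress variable; c=1 recovers the plain LJ interaction.
    """
    if eps == 0.0 or c == 0.0:
        return 0.0, 0.0
    sig2 = sig * sig
    rs2 = r2 + shift * (1.0 - c) * sig2
    s6 = (sig2 / rs2) ** 3
    u = c * 4.0 * eps * (s6 * s6 - s6)
    du = -c * 12.0 * eps * s6 * (2.0 * s6 - 1.0) / rs2
    return u, du


@njit(cache=True, fastmath=True)
def _energy_forces(
    pos, lam,
    pair_i, pair_j, pair_qq, pair_eps, pair_sig2, pair_wea, pair_web,
    pair_wva, pair_wvb, pair_soft,
    wall,
    kf_a, kf_b, anchor,
    bond_i, bond_j, bond_r0, bond_k,
    ang_i, ang_j, ang_k, ang_t0, ang_kt,
    r_on, r_off, sc_shift, k_wall, r_wall,
):
    """Return (components[5], forces[N,3]); components are
    (coulomb, lj, bonded, wall, anchor)."""
    n = pos.shape[0]
    n_pairs = pair_i.shape[0]
    f = np.zeros((n, 3))
    e_bond = 0.0
    e_wall = 0.0
    e_anchor = 0.0
    ron2 = r_on * r_on
    roff2 = r_off * r_off

    dxv = np.empty(n_pairs)
    dyv = np.empty(n_pairs)
    dzv = np.empty(n_pairs)
    r2v = np.empty(n_pairs)
    ucv = np.empty(n_pairs)
    ulv = np.empty(n_pairs)
    duv = np.empty(n_pairs)

    for p in range(n_pairs):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dxv[p] = dx
        dyv[p] = dy
        dzv[p] = dz
        r2v[p] = dx * dx + dy * dy + dz * dz

    # branch-free softcore Coulomb + LJ (the common case: r inside the
    # switching region; the rare switched/cut pairs are fixed up below)
    for p in range(n_pairs):
        r2 = r2v[p]
        sig2 = pair_sig2[p]
        we = pair_wea[p] + pair_web[p] * lam
        wv = pair_wva[p] + pair_wvb[p] * lam
        shift = pair_soft[p] * sc_shift
        # electrostatics: charge product scales linearly with coupling; the
        # same softcore distance shift as the LJ term caps the attractive
        # 1/r singularity of partially coupled pairs
        rc2 = r2 + shift * (1.0 - we) * sig2
        u_c = we * pair_qq[p] / np.sqrt(rc2)
        du_c = -0.5 * u_c / rc2
        # softcore 12-6: r^2 -> r^2 + shift*(1-w)*sigma^2
        rs2 = r2 + shift * (1.0 - wv) * sig2
        s6 = sig2 / rs2
        s6 = s6 * s6 * s6
        u_l = wv * 4.0 * pair_eps[p] * (s6 * s6 - s6)
        du_l = -wv * 12.0 * pair_eps[p] * s6 * (2.0 * s6 - 1.0) / rs2
        ucv[p] = u_c
        ulv[p] = u_l
        duv[p] = 2.0 * (du_c + du_l)

    # switching-region / cutoff fixup (rare for these compact droplets)
    for p in range(n_pairs):
        r2 = r2v[p]
        if r2 > ron2:
            if r2 >= roff2:
                ucv[p] = 0.0
                ulv[p] = 0.0
                duv[p] = 0.0
            else:
                s, ds = _switch(r2, ron2, roff2)
                du_bare = 0.5 * duv[p]
                duv[p] = 2.0 * (du_bare * s + (ucv[p] + ulv[p]) * ds)
                ucv[p] *= s
                ulv[p] *= s

    e_coul = 0.0
    e_lj = 0.0
    for p in range(n_pairs):
        e_coul += ucv[p]
        e_lj += ulv[p]
        i = pair_i[p]
        j = pair_j[p]
        du = duv[p]
        f[i, 0] -= du * dxv[p]
        f[i, 1] -= du * dyv[p]
        f[i, 2] -= du * dzv[p]
        f[j, 0] += du * dxv[p]
        f[j, 1] += du * dyv[p]
        f[j, 2] += du * dzv[p]

    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        e_bond += 0.5 * bond_k[b] * dr * dr
        if r > 0.0:
            g = bond_k[b] * dr / r
            f[i, 0] -= g * dx
            f[i, 1] -= g * dy
            f[i, 2] -= g * dz
            f[j, 0] += g * dx
            f[j, 1] += g * dy
            f[j, 2] += g * dz

    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        dth = theta - ang_t0[a]
        e_bond += 0.5 * ang_kt[a] * dth * dth
        st = np.sqrt(1.0 - c * c)
        if st < 1.0e-8:
            st = 1.0e-8
        coef = ang_kt[a] * dth
        # dtheta/dri = (c*uhat - vhat)/(|u| sin)
        gix = (c * ux / nu - vx / nv) / (nu * st)
        giy = (c * uy / nu - vy / nv) / (nu * st)
        giz = (c * uz / nu - vz / nv) / (nu * st)
        gkx = (c * vx / nv - ux / nu) / (nv * st)
        gky = (c * vy / nv - uy / nu) / (nv * st)
        gkz = (c * vz / nv - uz / nu) / (nv * st)
        f[i, 0] -= coef * gix
        f[i, 1] -= coef * giy
        f[i, 2] -= coef * giz
        f[k, 0] -= coef * gkx
        f[k, 1] -= coef * gky
        f[k, 2] -= coef * gkz
        f[j, 0] += coef * (gix + gkx)
        f[j, 1] += coef * (giy + gky)
        f[j, 2] += coef * (giz + gkz)

    for i in range(n):
        if wall[i] == 1:
            # one-sided wall centred on the ion (atom 0, fixed)
            dx = pos[i, 0] - pos[0, 0]
            dy = pos[i, 1] - pos[0, 1]
            dz = pos[i, 2] - pos[0, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > r_wall:
                over = d - r_wall
                e_wall += 0.5 * k_wall * over * over
                g = k_wall * over / d
                f[i, 0] -= g * dx
                f[i, 1] -= g * dy
                f[i, 2] -= g * dz
        kf = (1.0 - lam) * kf_a[i] + lam * kf_b[i]
        if kf > 0.0:
            dx = pos[i, 0] - anchor[i, 0]
            dy = pos[i, 1] - anchor[i, 1]
            dz = pos[i, 2] - anchor[i, 2]
            e_anchor += 0.5 * kf * (dx * dx + dy * dy + dz * dz)
            f[i, 0] -= kf * dx
            f[i, 1] -= kf * dy
            f[i, 2] -= kf * dz

    comps = np.empty(5)
    comps[0] = e_coul
    comps[1] = e_lj
    comps[2] = e_bond
    comps[3] = e_wall
    comps[4] = e_anchor
    return comps, f


def pair_energy(
    qi: float,
    qj: float,
    eps_ij: float,
    sigma_ij: float,
    r: float,
    params: NonbondedParams | None = None,
    lam_vdw: float = 1.0,
    lam_elec: float = 1.0,
) -> float:
    """Switched Coulomb + (softcore) Lennard-Jones energy of one pair, kcal/mol.

    ``lam_vdw`` scales and softens the LJ term (plain 12-6 at 1); ``lam_elec``
    scales the charge product linearly and, below 1, shares the softcore
    distance shift so that appearing/disappearing charged particles stay
    finite.  Finite for every r > 0 whenever ``lam_vdw < 1``.
    """
    params = params or NonbondedParams()
    if r <= 0.0:
        if lam_vdw >= 1.0:
            raise ZeroDivisionError("r = 0 with fully coupled LJ is singular")
        if lam_elec >= 1.0 and qi * qj != 0.0:
            raise ZeroDivisionError("r = 0 with fully coupled charges is singular")
    r2 = r * r
    roff2 = params.cutoff**2
    if r2 >= roff2:
        return 0.0
    s, _ = _switch(r2, params.switch_start**2, roff2)
    u_lj, _ = _lj_soft(eps_ij, sigma_ij, r2, lam_vdw, params.softcore_shift)
    rc2 = r2 + params.softcore_shift * (1.0 - lam_elec) * sigma_ij**2
    u_c = lam_elec * params.coulomb_constant * qi * qj / math.sqrt(rc2) if rc2 > 0 else 0.0
    return float((u_lj + u_c) * s)


def _eval(system, lam: float | None = None):
    packed = system.packed() if hasattr(system, "packed") else system
    lam_eff = packed_lambda(packed) if lam is None else float(lam)
    return _energy_forces(packed.pos, lam_eff, *packed.static_args()), packed


def packed_lambda(packed) -> float:
    return float(getattr(packed, "lam", 0.0))


def total_energy(system, lam: float | None = None) -> EnergyBreakdown:
    """Full potential-energy breakdown of a system at alchemical state ``lam``."""
    (comps, _), _ = _eval(system, lam)
    return EnergyBreakdown.from_array(comps)


def forces(system, lam: float | None = None) -> np.ndarray:
    """Analytic forces, kcal/mol/A.  The ion's force is reported but is never
    applied during dynamics (the ion is fixed)."""
    (_, f), _ = _eval(system, lam)
    return f


def restraint_energy(atom_position: np.ndarray, spec) -> EnergyBreakdown:
    """Wall + anchor restraint energy of a single atom against a RestraintSpec."""
    p = np.asarray(atom_position, dtype=float)
    d = float(np.linalg.norm(p - spec.center))
    wall = 0.0
    if d > spec.radius:
        wall = 0.5 * spec.k_wall * (d - spec.radius) ** 2
    anchor = 0.0
    if spec.kf > 0.0 and spec.anchor_position is not None:
        anchor = 0.5 * spec.kf * float(
            np.sum((p - np.asarray(spec.anchor_position, dtype=float)) ** 2)
        )
    return EnergyBreakdown(0.0, 0.0, 0.0, wall, anchor)
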