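"""Reproducible campaign orchestration.

A campaign turns a configuration (ion pair, ligand counts, kf grid, lambda
schedules, sampling scale, seeds) into tidy result tables: optimal radii,
selectivity-versus-kf curves, enthalpy/entropy decompositions, sampled
volumes, and transporter-site runs.  Every row carries the seed it was
generated from; a campaign re-run from its saved configuration and seeds is
bit-identical.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import asdict, dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .alchemy import (
    FULL_WINDOW_FS,
    KF_GRID,
    CycleResult,
    LambdaSchedule,
    assemble_cycle,
    hysteresis,
    run_ion_morph,
    run_restraint_morph,
)
from .errors import RdfNotConvergedError, UnsupportedCoordinationError
from .sampler import run_dynamics
from .systems import (
    anchor_geometry,
    build_abstract_system,
    build_site_model,
)
from .thermo import compute_rdf, occupancy_volume, rms_fluctuation

__all__ = [
    "CampaignConfig",
    "find_r_opt",
    "rlf_shift",
    "rlf_curve",
    "site_exchange_curve",
    "sampled_volume_change",
    "kf_to_rmsf",
]


@dataclass
class CampaignConfig:
    """Serialisable description of one campaign."""

    ion_pairs: list = field(default_factory=lambda: [["Na", "K"]])
    n_values: list = field(default_factory=lambda: [4, 5, 6, 7, 8])
    kf_grid: list = field(default_factory=lambda: list(KF_GRID))
    scale: float = 0.05
    seed: int = 0
    sites: list = field(default_factory=list)
    restraint_schedule: list = field(default_factory=lambda: [])
    ion_schedule: list = field(default_factory=lambda: [])
    out_dir: str = "results"
    schema_version: int = 1

    def __post_init__(self):
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")

    def nsteps_per_window(self) -> int:
        return max(1000, int(round(FULL_WINDOW_FS * self.scale)))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CampaignConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _scaled_steps(scale: float) -> int:
    return max(1000, int(round(FULL_WINDOW_FS * scale)))


def _subseed(seed: int, *key) -> int:
    """Stable (process-independent) derived seed below 2**31."""
    digest = hashlib.md5(repr((int(seed),) + tuple(key)).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def find_r_opt(ion: str, n: int, seed: int = 0, *, nsteps: int = 200_000,
               save_interval: int = 50, bin_width: float = 0.02,
               equil_frac: float = 0.1, check_convergence: bool = False) -> float:
    """Optimal ion-oxygen radius: first RDF peak of the unconstrained cage
    (wall only, no anchors).

    With ``check_convergence`` the two trajectory halves must agree on the
    peak position to within three bins, else :class:`RdfNotConvergedError`.
    """
    if not 4 <= n <= 8:
        raise UnsupportedCoordinationError(f"n={n} outside 4-8")
    system = build_abstract_system(ion, n)
    traj = run_dynamics(system, nsteps, _subseed(seed, "ropt", ion, n),
                        save_interval=save_interval)
    n_eq = int(math.ceil(equil_frac * traj.n_frames))

    def _sub(lo, hi):
        return _dc_replace(traj, frames=traj.frames[lo:hi],
                           times=traj.times[lo:hi],
                           components=traj.components[lo:hi],
                           kinetic=traj.kinetic[lo:hi], cross=traj.cross[lo:hi])

    prof = compute_rdf(_sub(n_eq, traj.n_frames), bin_width=bin_width)
    if check_convergence:
        mid = (n_eq + traj.n_frames) // 2
        p1 = compute_rdf(_sub(n_eq, mid), bin_width=bin_width).first_peak_r
        p2 = compute_rdf(_sub(mid, traj.n_frames), bin_width=bin_width).first_peak_r
        if abs(p1 - p2) > 3 * bin_width:
            raise RdfNotConvergedError(
                f"first peak moved {abs(p1 - p2):.3f} A between halves "
                f"({ion}, n={n}); extend the run"
            )
    return prof.first_peak_r


def r_opt_table(ions, n_values, seed: int = 0, **kw) -> pd.DataFrame:
    kw.setdefault("check_convergence", True)  # campaigns should fail loudly
    rows = []
    for ion in ions:
        for n in n_values:
            rows.append({"ion": ion, "n": n,
                         "R_opt_A": find_r_opt(ion, n, seed, **kw),
                         "seed": seed})
    return pd.DataFrame(rows)


def _constraint_leg(ion, n, kf, r_opt, scale, seed, *, direction="forward",
                    strained_anchor_ion=None, schedule=None):
    anchors = anchor_geometry(n, r_opt, ion=strained_anchor_ion or ion)
    return run_restraint_morph(
        ion, n, kf, anchors,
        schedule or LambdaSchedule.restraint_default(direction),
        seed=_subseed(seed, "constraint", ion, n, kf, direction,
                      strained_anchor_ion or ""),
        direction=direction,
        nsteps_per_window=_scaled_steps(scale),
        allow_strain=strained_anchor_ion is not None,
    )


def rlf_shift(ion_a: str, ion_b: str, n: int, kf: float, *, scale: float = 0.05,
              seed: int = 0, r_opts: dict | None = None,
              directions=("forward",)) -> dict:
    """ddG_RLF(kf) for one cage: both ions' restraint morphs at their own
    optimal radii.  Returns legs, value, and (with both directions)
    hysteresis."""
    r_opts = r_opts or {}
    legs = {}
    for ion in (ion_a, ion_b):
        r = r_opts.get(ion)
        if r is None:
            r = find_r_opt(ion, n, seed, nsteps=max(100_000, _scaled_steps(scale)))
            r_opts[ion] = r
        for direction in directions:
            legs[(ion, direction)] = _constraint_leg(ion, n, kf, r, scale, seed,
                                                     direction=direction)
    dg_a = legs[(ion_a, "forward")].signed()
    dg_b = legs[(ion_b, "forward")].signed()
    se = math.sqrt(legs[(ion_a, "forward")].se ** 2 + legs[(ion_b, "forward")].se ** 2)
    out = {
        "ion_a": ion_a, "ion_b": ion_b, "n": n, "kf": kf,
        "dG_constraint_A": dg_a, "dG_constraint_B": dg_b,
        "ddG_RLF": dg_b - dg_a, "se": se, "seed": seed,
        "r_opts": dict(r_opts), "legs": legs,
    }
    if "reverse" in directions:
        out["hysteresis"] = {
            ion: hysteresis(legs[(ion, "forward")], legs[(ion, "reverse")])
            for ion in (ion_a, ion_b)
        }
    ddh = legs[(ion_b, "forward")].signed_dH() - legs[(ion_a, "forward")].signed_dH()
    out["ddH_RLF"] = ddh
    out["minus_TddS_RLF"] = out["ddG_RLF"] - ddh
    return out


def rlf_curve(ion_a: str, ion_b: str, n: int, kf_grid=KF_GRID, *,
              scale: float = 0.05, seed: int = 0,
              include_exchange: bool = False,
              strained_anchor_ion: str | None = None,
              directions=("forward",)) -> pd.DataFrame:
    """ddG_RLF (and optionally ddG_exchange) versus kf for one cage pair.

    ``strained_anchor_ion`` reproduces the strained-cavity protocol: both
    ions anchored at that single ion's optimal geometry.
    """
    r_opts: dict = {}
    site_leg = None
    if include_exchange:
        site_leg = run_ion_morph(
            n, ion_a, ion_b,
            seed=_subseed(seed, "ionmorph", ion_a, ion_b, n),
            R_start=None, nsteps_per_window=_scaled_steps(scale),
        )
    rows = []
    for kf in kf_grid:
        if strained_anchor_ion is None:
            res = rlf_shift(ion_a, ion_b, n, kf, scale=scale, seed=seed,
                            r_opts=r_opts, directions=directions)
        else:
            r = r_opts.get(strained_anchor_ion)
            if r is None:
                r = find_r_opt(strained_anchor_ion, n, seed,
                               nsteps=max(100_000, _scaled_steps(scale)))
                r_opts[strained_anchor_ion] = r
            legs = {
                ion: _constraint_leg(ion, n, kf, r, scale, seed,
                                     strained_anchor_ion=strained_anchor_ion)
                for ion in (ion_a, ion_b)
            }
            res = {
                "ion_a": ion_a, "ion_b": ion_b, "n": n, "kf": kf,
                "dG_constraint_A": legs[ion_a].signed(),
                "dG_constraint_B": legs[ion_b].signed(),
                "ddG_RLF": legs[ion_b].signed() - legs[ion_a].signed(),
                "se": math.sqrt(legs[ion_a].se ** 2 + legs[ion_b].se ** 2),
                "seed": seed, "r_opts": dict(r_opts),
                "ddH_RLF": legs[ion_b].signed_dH() - legs[ion_a].signed_dH(),
            }
            res["minus_TddS_RLF"] = res["ddG_RLF"] - res["ddH_RLF"]
        row = {k: res[k] for k in
               ("ion_a", "ion_b", "n", "kf", "dG_constraint_A",
                "dG_constraint_B", "ddG_RLF", "ddH_RLF", "minus_TddS_RLF",
                "se", "seed")}
        row["windows"] = LambdaSchedule.restraint_default().n_windows
        if "hysteresis" in res:
            row["hysteresis_max"] = max(res["hysteresis"].values())
        if site_leg is not None:
            row["ddG_exchange"] = (row["dG_constraint_B"] - row["dG_constraint_A"]
                                   - site_leg.signed()
                                   + C.ddG_hydration(ion_a, ion_b))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# transporter sites


def site_cycles(site: str, ion_a: str, ion_b: str, kf_grid, *,
                scale: float = 0.05, seed: int = 0) -> list[CycleResult]:
    """Exchange cycles for a transporter-site model across the kf grid.

    Anchors come from per-ion energy minimisation of the site; the ion morph
    runs in the unanchored site.
    """
    model_a = build_site_model(site, ion_a)
    model_b = build_site_model(site, ion_b)
    n = model_a.n_ligands
    steps = _scaled_steps(scale)
    site_leg = run_ion_morph(
        n, ion_a, ion_b, seed=_subseed(seed, "site-ionmorph", site),
        nsteps_per_window=steps, system=model_a,
    )
    cycles = []
    for kf in kf_grid:
        leg_a = run_restraint_morph(
            ion_a, n, kf, None,
            seed=_subseed(seed, "site-constraint", site, ion_a, kf),
            nsteps_per_window=steps, system=model_a,
        )
        leg_b = run_restraint_morph(
            ion_b, n, kf, None,
            seed=_subseed(seed, "site-constraint", site, ion_b, kf),
            nsteps_per_window=steps, system=model_b,
        )
        cycles.append(assemble_cycle(leg_a, leg_b, site_leg))
    return cycles


def site_exchange_curve(site: str, ion_a: str, ion_b: str, kf_grid, *,
                        scale: float = 0.05, seed: int = 0) -> pd.DataFrame:
    rows = []
    for cyc in site_cycles(site, ion_a, ion_b, kf_grid, scale=scale, seed=seed):
        rows.append({
            "site": site, "ion_a": cyc.ion_a, "ion_b": cyc.ion_b,
            "n": cyc.n, "kf": cyc.kf,
            "ddG_exchange": cyc.ddG_exchange, "ddG_RLF": cyc.ddG_RLF,
            "ddH": cyc.ddH_constraint,
            "minus_TddS": cyc.ddG_RLF - cyc.ddH_constraint,
            "se": cyc.se, "seed": seed,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# volumes and fluctuations


def sampled_volume_change(ion: str, n: int, kf_low: float, kf_high: float, *,
                          seed: int = 0, nsteps: int = 100_000,
                          save_interval: int = 100, spacing: float = 0.1,
                          mode: str = "cumulative", all_atoms: bool = False,
                          r_opt: float | None = None) -> float:
    """Drop in cumulative sampled volume of the coordinating oxygens when kf
    rises from kf_low to kf_high (A^3); larger ions lose more volume."""
    if r_opt is None:
        r_opt = find_r_opt(ion, n, seed, nsteps=max(nsteps, 100_000))
    vols = {}
    for kf in (kf_low, kf_high):
        system = build_abstract_system(ion, n, R_opt=r_opt, kf=kf)
        traj = run_dynamics(system, nsteps, _subseed(seed, "vol", ion, n, kf),
                            save_interval=save_interval)
        atoms = None
        if all_atoms:
            atoms = np.where(traj.packed.mobile)[0]
        vols[kf] = occupancy_volume(traj, atoms=atoms, spacing=spacing, mode=mode)
    return vols[kf_low] - vols[kf_high]


def kf_to_rmsf(ion: str, n: int, kf_grid, *, seed: int = 0,
               nsteps: int = 50_000, save_interval: int = 50,
               r_opt: float | None = None) -> pd.DataFrame:
    """Pooled coordinating-oxygen RMSF per kf: the mapping from restraint
    stiffness onto observable fluctuation size."""
    if r_opt is None:
        r_opt = find_r_opt(ion, n, seed)
    rows = []
    for kf in kf_grid:
        system = build_abstract_system(ion, n, R_opt=r_opt, kf=kf)
        traj = run_dynamics(system, nsteps, _subseed(seed, "rmsf", ion, n, kf),
                            save_interval=save_interval)
        _, pooled = rms_fluctuation(traj)
        rows.append({"ion": ion, "n": n, "kf": kf, "rmsf_A": pooled,
                     "seed": seed})
    return pd.DataFrame(rows)
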