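"""Alchemical legs and the exchange thermodynamic cycle.

The selectivity of a coordination cage between ions A and B is quantified by
the free energy of the exchange reaction between the restrained site and
bulk water,

    ddG_exchange(kf) = dG_c,B(kf) - dG_c,A(kf) - dG_site(A->B) + ddG_hydr(A->B)

where ``dG_c,X`` is the restraint-morph free energy (anchored -> free cage
around ion X, the "morphing out" of the positional constraint), ``dG_site``
the ion-identity morph in the unanchored cage, and ``ddG_hydr`` the
bulk-water constant from tabulated hydration free energies.  Positive values
mean ion B is preferred in the site.  The part due purely to reduced ligand
fluctuations is

    ddG_RLF(kf) = ddG_exchange(kf) - ddG_exchange(0) = dG_c,B(kf) - dG_c,A(kf),

zero by definition at kf = 0 (the restraint morphs have identical
endpoints).

Free energies are estimated by exponential averaging (EXP) over adjacent
lambda windows, with Bennett acceptance-ratio (BAR) available as a
cross-check; forward/reverse hysteresis is the convergence diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from . import constants as C
from .errors import (
    CycleInconsistencyError,
    EstimatorError,
    InsufficientSamplingError,
    ProtocolError,
    StrainContaminationError,
)
from .sampler import run_dynamics
from .systems import (
    AnchorGeometry,
    ParticleSystem,
    build_abstract_system,
    make_ion_morph_system,
    make_kf_morph_system,
    make_restraint_morph_system,
)

#: Default restraint-morph schedule, dense at the endpoints where whole
#: ligand sets appear/disappear.
RESTRAINT_SCHEDULE = (
    (0.0, 1e-5, 1e-4, 1e-3, 1e-2)
    + tuple(round(0.05 * k, 2) for k in range(1, 20))
    + (0.99, 0.999, 0.9999, 0.99999, 1.0)
)

#: Default ion-morph schedule: 0 to 1 in 0.05 increments.
ION_SCHEDULE = tuple(round(0.05 * k, 2) for k in range(21))

#: Full-protocol sampling per window, fs (4 ns); campaigns apply a scale factor.
FULL_WINDOW_FS = 4_000_000

#: kf grid: 0 plus log10(kf) from -1 to 3 in 0.5 steps, kcal/mol/A^2.
KF_GRID = (0.0,) + tuple(round(10.0 ** (0.5 * k - 1.0), 4) for k in range(9))


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered lambda windows of one alchemical leg."""

    values: tuple[float, ...]
    direction: str = "forward"

    def __post_init__(self):
        v = self.values
        if self.direction not in ("forward", "reverse"):
            raise ValueError("direction must be forward or reverse")
        inc = all(b > a for a, b in zip(v, v[1:]))
        dec = all(b < a for a, b in zip(v, v[1:]))
        if not (inc or dec):
            raise ValueError("schedule must be strictly monotone")
        lo, hi = min(v), max(v)
        if lo != 0.0 or hi != 1.0:
            raise ValueError("schedule must span [0, 1] inclusive")
        if self.direction == "forward" and not inc:
            raise ValueError("forward schedule must increase")
        if self.direction == "reverse" and not dec:
            raise ValueError("reverse schedule must decrease")

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def reversed(self) -> "LambdaSchedule":
        return LambdaSchedule(
            tuple(reversed(self.values)),
            "reverse" if self.direction == "forward" else "forward",
        )

    @classmethod
    def restraint_default(cls, direction: str = "forward") -> "LambdaSchedule":
        s = cls(RESTRAINT_SCHEDULE)
        return s if direction == "forward" else s.reversed()

    @classmethod
    def ion_default(cls, direction: str = "forward") -> "LambdaSchedule":
        s = cls(ION_SCHEDULE)
        return s if direction == "forward" else s.reversed()


@dataclass
class FEPLegResult:
    """Per-window free-energy increments of one alchemical leg.

    ``total_dG`` is the window sum in the simulated direction (a reverse leg
    estimates G(lambda=0) - G(lambda=1)).  ``u_end_first``/``u_end_last`` are
    post-equilibration mean total potential energies of the first and last
    simulated windows, the raw material of the enthalpy decomposition.
    """

    leg_kind: str                      # restraint_morph | ion_morph | kf_morph | table
    ions: tuple[str, ...]
    n: int
    kf: float
    per_window_dG: np.ndarray
    per_window_se: np.ndarray
    direction: str
    seed: int
    samples_per_window: int
    schedule: LambdaSchedule | None = None
    u_end_first: float = math.nan
    u_end_last: float = math.nan
    estimator: str = "exp"
    meta: dict = field(default_factory=dict)

    @property
    def total_dG(self) -> float:
        return float(np.sum(self.per_window_dG))

    @property
    def se(self) -> float:
        return float(np.sqrt(np.sum(self.per_window_se**2)))

    @property
    def dH(self) -> float:
        """Endpoint-energy enthalpy estimate in the simulated direction."""
        return self.u_end_last - self.u_end_first

    def signed(self) -> float:
        """total_dG mapped onto the forward (lambda 0 -> 1) convention."""
        return self.total_dG if self.direction == "forward" else -self.total_dG

    def signed_dH(self) -> float:
        return self.dH if self.direction == "forward" else -self.dH


def _as_windows(table) -> list[np.ndarray]:
    if hasattr(table, "columns"):  # DataFrame: one column per window
        return [np.asarray(table[c], dtype=float) for c in table.columns]
    return [np.asarray(w, dtype=float) for w in table]


def _exp_increment(du: np.ndarray, kT: float, n_blocks: int = 10):
    """EXP estimate -kT ln<exp(-du/kT)> and a block standard error."""
    n = du.size
    if n < 10:
        raise InsufficientSamplingError(f"window has only {n} samples (< 10)")
    dg = -kT * (logsumexp(-du / kT) - math.log(n))
    nb = min(n_blocks, n // 2)
    blocks = np.array_split(du, nb)
    bg = np.array(
        [-kT * (logsumexp(-b / kT) - math.log(b.size)) for b in blocks]
    )
    se = float(np.std(bg, ddof=1) / math.sqrt(nb))
    return float(dg), se


def estimate_exp(table, schedule: LambdaSchedule | None = None,
                 T: float = C.T_DEFAULT, **leg_info) -> FEPLegResult:
    """Exponential-averaging (Zwanzig) estimator over adjacent windows.

    ``table`` holds, per window, samples of dU = U(next lambda) - U(this
    lambda); the per-window increments sum to the leg total.
    """
    kT = C.KB * T
    windows = _as_windows(table)
    dg = np.empty(len(windows))
    se = np.empty(len(windows))
    for i, du in enumerate(windows):
        dg[i], se[i] = _exp_increment(du, kT)
    return FEPLegResult(
        leg_kind=leg_info.pop("leg_kind", "table"),
        ions=tuple(leg_info.pop("ions", ())),
        n=leg_info.pop("n", 0),
        kf=leg_info.pop("kf", math.nan),
        per_window_dG=dg,
        per_window_se=se,
        direction=schedule.direction if schedule is not None else "forward",
        seed=leg_info.pop("seed", -1),
        samples_per_window=int(min(w.size for w in windows)),
        schedule=schedule,
        estimator="exp",
        meta=leg_info,
    )


def _bar_increment(w_f: np.ndarray, w_r: np.ndarray, kT: float,
                   max_iter: int = 10_000):
    """Bennett acceptance ratio for one window pair.

    ``w_f``: samples of U1-U0 drawn in state 0; ``w_r``: samples of U0-U1
    drawn in state 1.  Returns (dG, se).
    """
    nf, nr = w_f.size, w_r.size
    if nf < 10 or nr < 10:
        raise InsufficientSamplingError("BAR window with < 10 samples")
    m = math.log(nf / nr)
    beta = 1.0 / kT

    def g(df):
        a = 1.0 / (1.0 + np.exp(np.clip(m + beta * (w_f - df), -500, 500)))
        b = 1.0 / (1.0 + np.exp(np.clip(-m + beta * (w_r + df), -500, 500)))
        return np.sum(a) - np.sum(b)

    lo = min(float(np.min(w_f)), float(-np.max(w_r))) - 50.0 * kT
    hi = max(float(np.max(w_f)), float(-np.min(w_r))) + 50.0 * kT
    it = 0
    while g(lo) * g(hi) > 0:
        lo -= 100.0 * kT
        hi += 100.0 * kT
        it += 1
        if it > 100:
            raise EstimatorError("BAR self-consistency equation has no bracket")
    try:
        df = brentq(g, lo, hi, xtol=1e-12, maxiter=max_iter)
    except RuntimeError as exc:  # pragma: no cover
        raise EstimatorError(f"BAR failed to converge: {exc}") from exc
    # Bennett variance at the solution, with the sample counts deflated by
    # the statistical inefficiency of the (time-correlated) work series
    ff = 1.0 / (1.0 + np.exp(np.clip(m + beta * (w_f - df), -500, 500)))
    fr = 1.0 / (1.0 + np.exp(np.clip(-m + beta * (w_r + df), -500, 500)))
    vf = float(np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / (nf / _stat_ineff(w_f))
    vr = float(np.mean(fr**2) / np.mean(fr) ** 2 - 1.0) / (nr / _stat_ineff(w_r))
    se = kT * math.sqrt(max(vf + vr, 0.0))
    return float(df), se


def _stat_ineff(x: np.ndarray, max_lag: int | None = None) -> float:
    """Integrated-autocorrelation statistical inefficiency g >= 1."""
    n = x.size
    if n < 4 or np.var(x) == 0:
        return 1.0
    xc = x - x.mean()
    var = float(np.dot(xc, xc)) / n
    g = 1.0
    max_lag = max_lag or min(n // 2, 200)
    for t in range(1, max_lag):
        c = float(np.dot(xc[:-t], xc[t:])) / ((n - t) * var)
        if c <= 0:
            break
        g += 2.0 * c * (1.0 - t / n)
    return max(g, 1.0)


def estimate_bar(forward_table, reverse_table, T: float = C.T_DEFAULT,
                 schedule: LambdaSchedule | None = None, **leg_info) -> FEPLegResult:
    """Bennett acceptance-ratio estimator over matched window pairs.

    ``forward_table[i]``: dU = U(i+1)-U(i) sampled in window i;
    ``reverse_table[i]``: dU = U(i)-U(i+1) sampled in window i+1.
    """
    kT = C.KB * T
    fw = _as_windows(forward_table)
    rv = _as_windows(reverse_table)
    if len(fw) != len(rv):
        raise ValueError("forward and reverse tables must pair up per window")
    dg = np.empty(len(fw))
    se = np.empty(len(fw))
    for i, (wf, wr) in enumerate(zip(fw, rv)):
        dg[i], se[i] = _bar_increment(wf, wr, kT)
    return FEPLegResult(
        leg_kind=leg_info.pop("leg_kind", "table"),
        ions=tuple(leg_info.pop("ions", ())),
        n=leg_info.pop("n", 0),
        kf=leg_info.pop("kf", math.nan),
        per_window_dG=dg,
        per_window_se=se,
        direction=schedule.direction if schedule is not None else "forward",
        seed=leg_info.pop("seed", -1),
        samples_per_window=int(min(min(w.size for w in fw), min(w.size for w in rv))),
        schedule=schedule,
        estimator="bar",
        meta=leg_info,
    )


# ---------------------------------------------------------------------------
# leg execution


def _window_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((int(seed), int(index))).generate_state(1)[0]
               % (2**31 - 1))


@dataclass
class LegSamples:
    """Raw cross-energy samples of one simulated leg."""

    schedule: LambdaSchedule
    du_next: list          # per window i: U(lam[i+1]) - U(lam[i]) samples (None for last)
    du_prev: list          # per window i: U(lam[i-1]) - U(lam[i]) samples (None for first)
    u_mean: np.ndarray     # post-equilibration mean potential per window

    def forward_increments(self):
        return self.du_next[:-1]

    def reverse_increments(self):
        """Aligned with forward: samples of U(i)-U(i+1) drawn in window i+1."""
        return self.du_prev[1:]


def simulate_leg(system: ParticleSystem, schedule: LambdaSchedule,
                 nsteps_per_window: int, seed: int, *, save_interval: int = 100,
                 equil_frac: float = 0.1) -> LegSamples:
    """Walk the lambda ladder, handing coordinates window to window, and
    collect cross-evaluated energy differences to both neighbours."""
    vals = schedule.values
    k = len(vals)
    pos = None
    vel = None
    du_next: list = [None] * k
    du_prev: list = [None] * k
    u_mean = np.empty(k)
    for i, lam in enumerate(vals):
        evals = []
        if i > 0:
            evals.append(vals[i - 1])
        if i < k - 1:
            evals.append(vals[i + 1])
        traj = run_dynamics(
            system, nsteps_per_window, _window_seed(seed, i),
            save_interval=save_interval, lam=lam, lam_evals=tuple(evals),
            pos0=pos, vel0=vel,
        )
        pos, vel = traj.final_pos, traj.final_vel
        n_eq = int(math.ceil(equil_frac * traj.n_frames))
        u_self = traj.potential[n_eq:]
        u_mean[i] = float(np.mean(u_self))
        col = 0
        if i > 0:
            du_prev[i] = traj.cross[n_eq:, col] - u_self
            col += 1
        if i < k - 1:
            du_next[i] = traj.cross[n_eq:, col] - u_self
    return LegSamples(schedule=schedule, du_next=du_next, du_prev=du_prev,
                      u_mean=u_mean)


def _leg_from_samples(samples: LegSamples, T: float, estimator: str,
                      **leg_info) -> FEPLegResult:
    if estimator == "exp":
        res = estimate_exp(samples.forward_increments(), samples.schedule, T,
                           **leg_info)
    elif estimator == "bar":
        res = estimate_bar(samples.forward_increments(),
                           samples.reverse_increments(), T,
                           schedule=samples.schedule, **leg_info)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    res.u_end_first = float(samples.u_mean[0])
    res.u_end_last = float(samples.u_mean[-1])
    return res


def run_leg(system: ParticleSystem, schedule: LambdaSchedule,
            nsteps_per_window: int, seed: int, *, estimator: str = "exp",
            save_interval: int = 100, equil_frac: float = 0.1,
            **leg_info) -> FEPLegResult:
    samples = simulate_leg(system, schedule, nsteps_per_window, seed,
                           save_interval=save_interval, equil_frac=equil_frac)
    leg_info.setdefault("seed", seed)
    return _leg_from_samples(samples, system.temperature, estimator, **leg_info)


def _zero_leg(kind, ions, n, kf, schedule, seed) -> FEPLegResult:
    nw = schedule.n_windows - 1
    return FEPLegResult(
        leg_kind=kind, ions=ions, n=n, kf=kf,
        per_window_dG=np.zeros(nw), per_window_se=np.zeros(nw),
        direction=schedule.direction, seed=seed, samples_per_window=0,
        schedule=schedule, u_end_first=0.0, u_end_last=0.0,
        meta={"trivial": "identical endpoints (kf = 0)"},
    )


def run_restraint_morph(
    ion: str,
    n: int,
    kf_target: float,
    anchors: AnchorGeometry,
    schedule: LambdaSchedule | None = None,
    seed: int = 0,
    direction: str = "forward",
    *,
    nsteps_per_window: int = 20_000,
    save_interval: int = 100,
    estimator: str = "exp",
    allow_strain: bool = False,
    system: ParticleSystem | None = None,
    temperature: float = C.T_DEFAULT,
) -> FEPLegResult:
    """Dual-topology restraint morph: anchored cage (lambda=0) to free cage
    (lambda=1) around a single ion; returns the constraint free energy
    dG_c = G_free - G_anchored.

    Anchors must derive from the simulated ion's own optimal geometry; using
    another ion's anchors is the strained-cavity protocol and must be
    requested explicitly with ``allow_strain=True``.
    """
    if anchors is not None and anchors.ion is not None and anchors.ion != ion:
        if not allow_strain:
            raise StrainContaminationError(
                f"anchors were built for {anchors.ion}, but {ion} is simulated; "
                "pass allow_strain=True for the strained-cavity protocol"
            )
    if (system is not None and system.anchor_ion is not None
            and system.anchor_ion != ion and not allow_strain):
        raise StrainContaminationError(
            f"system anchors derive from {system.anchor_ion}, but {ion} is "
            "simulated; pass allow_strain=True for the strained-cavity protocol"
        )
    schedule = schedule or LambdaSchedule.restraint_default(direction)
    if kf_target == 0.0:
        return _zero_leg("restraint_morph", (ion,), n, 0.0, schedule, seed)
    if system is None:
        base = build_abstract_system(ion, n, anchors=anchors,
                                     temperature=temperature)
    else:
        base = system
    dual = make_restraint_morph_system(base, kf_target)
    return run_leg(dual, schedule, nsteps_per_window, seed,
                   estimator=estimator, save_interval=save_interval,
                   leg_kind="restraint_morph", ions=(ion,), n=n, kf=kf_target)


def run_ion_morph(
    n: int,
    ion_a: str,
    ion_b: str,
    schedule: LambdaSchedule | None = None,
    seed: int = 0,
    *,
    R_start: float | None = None,
    nsteps_per_window: int = 20_000,
    save_interval: int = 100,
    estimator: str = "exp",
    system: ParticleSystem | None = None,
    temperature: float = C.T_DEFAULT,
) -> FEPLegResult:
    """Ion-identity morph A -> B in the unanchored (wall-only) cage.

    The ion's Lennard-Jones interaction interpolates by dual softcore
    evaluation; the charge stays +1 throughout.
    """
    schedule = schedule or LambdaSchedule.ion_default()
    if system is None:
        base = build_abstract_system(ion_a, n, R_opt=R_start,
                                     temperature=temperature)
    else:
        if system.ion_species != ion_a:
            raise ProtocolError("system ion does not match ion_a")
        base = replace(system, kf=np.zeros_like(system.kf),
                       kf_end=np.zeros_like(system.kf_end))
        if np.any(system.kf > 0):
            raise ProtocolError("ion morphs require an unanchored system")
    morph = make_ion_morph_system(base, ion_b)
    return run_leg(morph, schedule, nsteps_per_window, seed,
                   estimator=estimator, save_interval=save_interval,
                   leg_kind="ion_morph", ions=(ion_a, ion_b), n=n, kf=0.0)


def run_kf_morph(
    system: ParticleSystem,
    kf_start: float,
    kf_end: float,
    schedule: LambdaSchedule | None = None,
    seed: int = 0,
    *,
    nsteps_per_window: int = 20_000,
    save_interval: int = 100,
    estimator: str = "exp",
) -> FEPLegResult:
    """Single-set morph interpolating anchor stiffness linearly in lambda;
    the analytic-oracle path (its value is the physical confinement free
    energy)."""
    schedule = schedule or LambdaSchedule(tuple(round(0.1 * k, 1) for k in range(11)))
    morph = make_kf_morph_system(system, kf_start, kf_end)
    return run_leg(morph, schedule, nsteps_per_window, seed,
                   estimator=estimator, save_interval=save_interval,
                   leg_kind="kf_morph", ions=(system.ion_species,),
                   n=system.n_ligands, kf=kf_end)


# ---------------------------------------------------------------------------
# cycle assembly


@dataclass(frozen=True)
class CycleResult:
    """Assembled exchange free energy for an ion pair at one kf.

    Sign convention: positive means ion B is preferred in the site.
    """

    ion_a: str
    ion_b: str
    n: int
    kf: float
    dG_constraint_A: float
    dG_constraint_B: float
    dG_site_exchange: float
    ddG_hydr: float
    se: float = 0.0
    ddH_constraint: float = math.nan

    @property
    def ddG_exchange(self) -> float:
        return (self.dG_constraint_B - self.dG_constraint_A
                - self.dG_site_exchange + self.ddG_hydr)

    @property
    def ddG_RLF(self) -> float:
        """kf-dependent part; the ion-morph and hydration legs cancel against
        the kf = 0 reference, whose restraint morphs are identically zero."""
        return self.dG_constraint_B - self.dG_constraint_A


def assemble_cycle(constraint_A: FEPLegResult, constraint_B: FEPLegResult,
                   site_exchange: FEPLegResult,
                   ddG_hydr: float | None = None) -> CycleResult:
    """Pure-arithmetic assembly of ddG_exchange from its component legs."""
    if constraint_A.n != constraint_B.n or constraint_A.n != site_exchange.n:
        raise CycleInconsistencyError("legs disagree on ligand count n")
    ion_a, ion_b = site_exchange.ions
    if constraint_A.ions != (ion_a,) or constraint_B.ions != (ion_b,):
        raise CycleInconsistencyError(
            f"constraint legs {constraint_A.ions}/{constraint_B.ions} do not "
            f"match exchange leg {site_exchange.ions}"
        )
    if constraint_A.kf != constraint_B.kf:
        raise CycleInconsistencyError("constraint legs disagree on kf")
    if ddG_hydr is None:
        ddG_hydr = C.ddG_hydration(ion_a, ion_b)
    se = math.sqrt(constraint_A.se**2 + constraint_B.se**2 + site_exchange.se**2)
    ddh = math.nan
    if math.isfinite(constraint_A.dH) and math.isfinite(constraint_B.dH):
        ddh = constraint_B.signed_dH() - constraint_A.signed_dH()
    return CycleResult(
        ion_a=ion_a, ion_b=ion_b, n=site_exchange.n, kf=constraint_A.kf,
        dG_constraint_A=constraint_A.signed(),
        dG_constraint_B=constraint_B.signed(),
        dG_site_exchange=site_exchange.signed(),
        ddG_hydr=float(ddG_hydr), se=se, ddH_constraint=ddh,
    )


def hysteresis(forward: FEPLegResult, reverse: FEPLegResult) -> float:
    """Sign-aligned forward/reverse disagreement |dG_fw + dG_rv|, kcal/mol."""
    if forward.direction == reverse.direction:
        raise ValueError("hysteresis needs one forward and one reverse leg")
    return abs(forward.total_dG + reverse.total_dG)


def hysteresis_summary(pairs) -> tuple[float, float]:
    """(max, mean) hysteresis over a campaign's matched leg pairs."""
    h = [hysteresis(f, r) for f, r in pairs]
    if not h:
        return (math.nan, math.nan)
    return (float(np.max(h)), float(np.mean(h)))
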