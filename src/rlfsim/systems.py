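"""Construction of every simulatable object: ligand templates, anchor
geometries, abstract ion-coordination cages, transporter-site models, and
analytic-oracle toy systems.

An abstract cage is one fixed monovalent cation at the origin surrounded by
``n`` small dipolar ligands whose coordinating oxygens are confined to a
3.5 Angstrom flat-bottom sphere.  Ligand thermal fluctuations are reduced by
per-atom harmonic anchors of force constant ``kf`` placed at each ion's own
optimal geometry (no strain).  Transporter-site models replace the uniform
ligand set with the composition of real Na+ binding sites (carbonyls,
hydroxyls, carboxylate) and define anchor positions by per-ion energy
minimisation of an idealised starting geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import constants as C
from .energetics import NonbondedParams, PackedSystem, _energy_forces
from .errors import (
    ConstructionClashError,
    DivergenceError,
    FixtureNotFoundError,
    UnsupportedCoordinationError,
    UnsupportedTemplateError,
)

__all__ = [
    "Atom",
    "LigandTemplate",
    "AnchorGeometry",
    "RestraintSpec",
    "ParticleSystem",
    "build_ligand_template",
    "anchor_geometry",
    "pack_points_on_sphere",
    "build_abstract_system",
    "build_site_model",
    "make_restraint_morph_system",
    "make_ion_morph_system",
    "make_kf_morph_system",
    "toy_anchored_atom",
    "toy_ideal_cage",
    "toy_ideal_gas",
    "minimise",
]


@dataclass(frozen=True)
class Atom:
    type_name: str
    element: str
    charge: float
    epsilon: float
    sigma: float
    mass: float


def _atom(type_name: str) -> Atom:
    try:
        row = C.atom_params().loc[type_name]
    except KeyError:
        raise UnsupportedTemplateError(f"no parameters for atom type {type_name!r}")
    return Atom(
        type_name,
        str(row["element"]),
        float(row["charge_e"]),
        float(row["epsilon_kcal_mol"]),
        float(row["sigma_A"]),
        float(row["mass_amu"]),
    )


@dataclass(frozen=True)
class LigandTemplate:
    """A small dipolar ligand fragment with internal geometry.

    ``coords`` places the coordinating point (single coordinating oxygen, or
    the midpoint of the two carboxylate oxygens) at the origin with the
    outward direction along +z, so placement is a rotation plus translation.
    """

    name: str
    atoms: tuple[Atom, ...]
    coords: np.ndarray                      # (natoms, 3) ideal geometry
    bonds: tuple[tuple[int, int, float, float], ...]     # i, j, r0, k
    angles: tuple[tuple[int, int, int, float, float], ...]  # i, j, k, theta0(rad), k
    coordinating: tuple[int, ...]           # indices of walled oxygens

    @property
    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def validate(self):
        q = sum(a.charge for a in self.atoms)
        if abs(q - round(q)) > 1e-12:
            raise UnsupportedTemplateError(
                f"{self.name}: partial charges sum to {q}, not an integer"
            )
        nat = self.n_atoms
        for i, j, *_ in self.bonds:
            if not (0 <= i < nat and 0 <= j < nat):
                raise UnsupportedTemplateError(f"{self.name}: bond references missing atom")
        for i, j, k, *_ in self.angles:
            if not all(0 <= x < nat for x in (i, j, k)):
                raise UnsupportedTemplateError(f"{self.name}: angle references missing atom")
        if len(self.coordinating) not in (1, 2):
            raise UnsupportedTemplateError(
                f"{self.name}: expected 1 (monodentate) or 2 (bidentate) coordinating atoms"
            )


def _bonded(kind: str, *types: str) -> tuple[float, float]:
    df = C.bonded_params()
    cols = ["a", "b"] if kind == "bond" else ["a", "b", "c"]
    sel = df[df["kind"] == kind]
    for _, row in sel.iterrows():
        if tuple(row[c] for c in cols) == types:
            return float(row["ref"]), float(row["k"])
    raise UnsupportedTemplateError(f"no {kind} parameters for {types}")


def _carbonyl_template(name: str, c_type: str, o_type: str, h_type: str) -> LigandTemplate:
    r_co, k_co = _bonded("bond", c_type, o_type)
    r_ch, k_ch = _bonded("bond", c_type, h_type)
    t_och, k_och = _bonded("angle", o_type, c_type, h_type)
    t_hch, k_hch = _bonded("angle", h_type, c_type, h_type)
    a = math.radians(180.0 - t_och)  # H direction polar angle from the C->out axis
    coords = np.array(
        [
            [0.0, 0.0, r_co],                                  # C
            [0.0, 0.0, 0.0],                                   # O (coordinating)
            [r_ch * math.sin(a), 0.0, r_co + r_ch * math.cos(a)],
            [-r_ch * math.sin(a), 0.0, r_co + r_ch * math.cos(a)],
        ]
    )
    return LigandTemplate(
        name=name,
        atoms=(_atom(c_type), _atom(o_type), _atom(h_type), _atom(h_type)),
        coords=coords,
        bonds=((0, 1, r_co, k_co), (0, 2, r_ch, k_ch), (0, 3, r_ch, k_ch)),
        angles=(
            (1, 0, 2, math.radians(t_och), k_och),
            (1, 0, 3, math.radians(t_och), k_och),
            (2, 0, 3, math.radians(t_hch), k_hch),
        ),
        coordinating=(1,),
    )


def build_ligand_template(kind: str) -> LigandTemplate:
    """Build one of the supported dipolar ligand fragments.

    ``formaldehyde_like`` is the abstract-cage ligand (C +0.5, O -0.5, H 0.0);
    ``backbone_carbonyl``, ``hydroxyl`` and ``carboxylate`` are the
    transporter-site fragments.  The carboxylate is bidentate (both oxygens
    coordinate).
    """
    if kind == "formaldehyde_like":
        t = _carbonyl_template("formaldehyde_like", "FC", "FO", "FH")
    elif kind == "backbone_carbonyl":
        t = _carbonyl_template("backbone_carbonyl", "BC", "BO", "BH")
    elif kind == "hydroxyl":
        r_co, k_co = _bonded("bond", "HC", "HO")
        r_oh, k_oh = _bonded("bond", "HO", "HH")
        t_coh, k_coh = _bonded("angle", "HC", "HO", "HH")
        a = math.radians(t_coh)
        coords = np.array(
            [
                [0.0, 0.0, r_co],                              # C
                [0.0, 0.0, 0.0],                               # O (coordinating)
                [r_oh * math.sin(a), 0.0, r_oh * math.cos(a)], # H
            ]
        )
        t = LigandTemplate(
            name="hydroxyl",
            atoms=(_atom("HC"), _atom("HO"), _atom("HH")),
            coords=coords,
            bonds=((0, 1, r_co, k_co), (1, 2, r_oh, k_oh)),
            angles=((0, 1, 2, math.radians(t_coh), k_coh),),
            coordinating=(1,),
        )
    elif kind == "carboxylate":
        r_bc, k_bc = _bonded("bond", "XB", "XC")
        r_co, k_co = _bonded("bond", "XC", "XO")
        t_bco, k_bco = _bonded("angle", "XB", "XC", "XO")
        t_oco, k_oco = _bonded("angle", "XO", "XC", "XO")
        half = math.radians(t_oco) / 2.0
        z_c = r_co * math.cos(half)  # carbon sits above the O-O midpoint
        coords = np.array(
            [
                [0.0, 0.0, z_c + r_bc],                        # CB
                [0.0, 0.0, z_c],                               # C (carboxyl)
                [r_co * math.sin(half), 0.0, 0.0],             # O1
                [-r_co * math.sin(half), 0.0, 0.0],            # O2
            ]
        )
        t = LigandTemplate(
            name="carboxylate",
            atoms=(_atom("XB"), _atom("XC"), _atom("XO"), _atom("XO")),
            coords=coords,
            bonds=((0, 1, r_bc, k_bc), (1, 2, r_co, k_co), (1, 3, r_co, k_co)),
            angles=(
                (0, 1, 2, math.radians(t_bco), k_bco),
                (0, 1, 3, math.radians(t_bco), k_bco),
                (2, 1, 3, math.radians(t_oco), k_oco),
            ),
            coordinating=(2, 3),
        )
    else:
        raise UnsupportedTemplateError(f"unknown ligand kind {kind!r}")
    t.validate()
    return t


# ---------------------------------------------------------------------------
# anchor geometries


@dataclass(frozen=True)
class AnchorGeometry:
    """n directions on a sphere of radius R where coordinating atoms anchor.

    ``ion`` records which ion's optimal radius produced R; restraint morphs
    refuse anchors built for a different ion unless strain is explicit.
    """

    n: int
    radius: float
    points: np.ndarray            # (n, 3), |p| = R
    source: str                   # polyhedron | sphere_packing | minimised_site
    ion: str | None = None

    def min_pair_angle(self) -> float:
        """Minimum pairwise angular separation, degrees."""
        u = self.points / np.linalg.norm(self.points, axis=1, keepdims=True)
        cosmax = -1.0
        for i in range(self.n - 1):
            c = u[i + 1:] @ u[i]
            cosmax = max(cosmax, float(np.max(c)))
        return math.degrees(math.acos(min(1.0, max(-1.0, cosmax))))


def _polyhedron_unit(n: int, eight_fold: str = "square_antiprism") -> np.ndarray:
    if n == 4:
        v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        return v / math.sqrt(3.0)
    if n == 6:
        return np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
    if n == 8:
        if eight_fold == "cube":
            v = np.array(
                [[sx, sy, sz] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)],
                dtype=float,
            )
            return v / math.sqrt(3.0)
        # square antiprism at the max-min-angle latitude: tan^2(theta) = sqrt(2)/4
        theta = math.atan(2.0 ** 0.25 / 2.0)
        rho, z = math.cos(theta), math.sin(theta)
        pts = []
        for k in range(4):
            phi = k * math.pi / 2.0
            pts.append([rho * math.cos(phi), rho * math.sin(phi), z])
        for k in range(4):
            phi = k * math.pi / 2.0 + math.pi / 4.0
            pts.append([rho * math.cos(phi), rho * math.sin(phi), -z])
        return np.array(pts)
    raise UnsupportedCoordinationError(f"no closed-form polyhedron for n={n}")


def pack_points_on_sphere(n: int, seed: int = 0, n_iter: int = 100_000,
                          restarts: int = 4, exponent: float = 12.0) -> np.ndarray:
    """Deterministic repulsion optimisation of n unit vectors (Tammes-style).

    Projected gradient descent on sum of inverse-power chord repulsions with a
    decaying step size; several seeded restarts, best (largest minimum
    separation) kept.  For n = 4 and 6 this converges to the tetrahedron and
    octahedron to well below 1e-3 degrees.
    """
    best = None
    best_min = -1.0
    for r in range(restarts):
        rng = np.random.default_rng(seed + 1000 * r)
        x = rng.standard_normal((n, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step = 0.05
        for it in range(n_iter):
            diff = x[:, None, :] - x[None, :, :]            # (n,n,3)
            d2 = np.sum(diff * diff, axis=-1)
            np.fill_diagonal(d2, np.inf)
            w = d2 ** (-(exponent / 2.0 + 1.0))
            grad = -exponent * np.sum(w[:, :, None] * diff, axis=1)
            x = x - step * grad / (np.linalg.norm(grad, axis=1, keepdims=True) + 1e-12)
            x /= np.linalg.norm(x, axis=1, keepdims=True)
            if it % 2000 == 1999:
                step *= 0.7
        dmin = np.sqrt(np.min(np.where(np.eye(n, dtype=bool), np.inf,
                                       np.sum((x[:, None] - x[None]) ** 2, axis=-1))))
        if dmin > best_min:
            best_min = dmin
            best = x
    return best


def anchor_geometry(n: int, radius: float, *, ion: str | None = None,
                    eight_fold: str = "square_antiprism",
                    seed: int = 0) -> AnchorGeometry:
    """Anchor directions for an n-coordinate cage at radius R (Angstrom).

    n = 4, 6, 8 use exact polyhedron vertices (tetrahedron, octahedron,
    square antiprism by default); n = 5, 7 use the deterministic
    sphere-packing optimiser.
    """
    if not 4 <= n <= 8:
        raise UnsupportedCoordinationError(f"n={n} outside the supported range 4-8")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n in (4, 6, 8):
        unit = _polyhedron_unit(n, eight_fold)
        source = "polyhedron"
    else:
        unit = pack_points_on_sphere(n, seed=seed)
        source = "sphere_packing"
    return AnchorGeometry(n=n, radius=radius, points=unit * radius,
                          source=source, ion=ion)


# ---------------------------------------------------------------------------
# restraints and particle systems


@dataclass(frozen=True)
class RestraintSpec:
    """One-sided spherical wall plus an optional harmonic anchor for one atom."""

    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = C.WALL_RADIUS
    k_wall: float = C.K_WALL_DEFAULT
    kf: float = 0.0
    anchor_position: np.ndarray | None = None

    def __post_init__(self):
        if self.kf < 0:
            raise ValueError("kf must be >= 0")
        if self.kf > 0 and self.anchor_position is None:
            raise ValueError("anchors require an anchor position")


@dataclass
class ParticleSystem:
    """One fixed central ion plus ligand atoms with restraints and an
    alchemical mode.  ``set_id`` 0 marks the environment/anchored set, 1 the
    free set of a dual-topology restraint morph."""

    ion_species: str
    coords: np.ndarray               # ligand atoms only, (N,3)
    atoms: tuple[Atom, ...]          # per ligand atom
    ligand_id: np.ndarray            # (N,) int
    set_id: np.ndarray               # (N,) int in {0,1}
    coordinating: np.ndarray         # (N,) bool  (walled atoms)
    bonds: np.ndarray                # (nb,2) int + parallel r0,k arrays
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray               # (na,3) int
    angle_t0: np.ndarray
    angle_k: np.ndarray
    kf: np.ndarray                   # per-atom anchor force constants (lambda=0)
    kf_end: np.ndarray               # per-atom anchor force constants (lambda=1)
    anchor_pos: np.ndarray           # (N,3)
    mode: str = "none"               # none | dual_restraint | ion_morph | kf_morph
    ion_species_b: str | None = None # ion morph target
    k_wall: float = C.K_WALL_DEFAULT
    wall_radius: float = C.WALL_RADIUS
    temperature: float = C.T_DEFAULT
    nb: NonbondedParams = field(default_factory=NonbondedParams)
    ligand_kinds: tuple[str, ...] = ()
    anchor_ion: str | None = None    # which ion's optimum the anchors derive from

    # -- derived ---------------------------------------------------------

    @property
    def n_ligands(self) -> int:
        mask = self.set_id == 0
        return len(np.unique(self.ligand_id[mask]))

    @property
    def n_atoms(self) -> int:
        """Ligand atoms plus the ion."""
        return self.coords.shape[0] + 1

    @property
    def total_charge(self) -> float:
        ion = _atom(C.ion_type_name(self.ion_species))
        return float(ion.charge + sum(a.charge for a in self.atoms))

    def ion_atom(self) -> Atom:
        return _atom(C.ion_type_name(self.ion_species))

    def packed(self) -> PackedSystem:
        ion = self.ion_atom()
        n = self.n_atoms
        pos = np.vstack([np.zeros(3), self.coords])
        charge = np.concatenate([[ion.charge], [a.charge for a in self.atoms]])
        eps = np.concatenate([[ion.epsilon], [a.epsilon for a in self.atoms]])
        sig = np.concatenate([[ion.sigma], [a.sigma for a in self.atoms]])
        mass = np.concatenate([[ion.mass], [a.mass for a in self.atoms]])
        eps_b, sig_b = eps.copy(), sig.copy()
        morph_ion = False
        if self.mode == "ion_morph":
            if self.ion_species_b is None:
                raise ValueError("ion morph requires ion_species_b")
            ion_b = _atom(C.ion_type_name(self.ion_species_b))
            eps_b[0], sig_b[0] = ion_b.epsilon, ion_b.sigma
            morph_ion = True
        group = np.zeros(n, dtype=np.int64)
        if self.mode == "dual_restraint":
            group[1:][self.set_id == 0] = 1   # anchored set: outgoing
            group[1:][self.set_id == 1] = 2   # free set: incoming
        ligid = np.concatenate([[-1], self.ligand_id]).astype(np.int64)
        wall = np.concatenate([[False], self.coordinating])
        kf_a = np.concatenate([[0.0], self.kf])
        kf_b = np.concatenate([[0.0], self.kf_end])
        anchor = np.vstack([np.zeros(3), self.anchor_pos])
        mobile = np.ones(n, dtype=bool)
        mobile[0] = False
        off = 1  # ion occupies slot 0
        bi = (self.bonds[:, 0] + off).astype(np.int64) if len(self.bonds) else np.empty(0, np.int64)
        bj = (self.bonds[:, 1] + off).astype(np.int64) if len(self.bonds) else np.empty(0, np.int64)
        ai = (self.angles[:, 0] + off).astype(np.int64) if len(self.angles) else np.empty(0, np.int64)
        aj = (self.angles[:, 1] + off).astype(np.int64) if len(self.angles) else np.empty(0, np.int64)
        ak = (self.angles[:, 2] + off).astype(np.int64) if len(self.angles) else np.empty(0, np.int64)
        ps = PackedSystem(
            pos=pos, charge=charge, eps_a=eps, sig_a=sig, eps_b=eps_b, sig_b=sig_b,
            group=group, ligand_id=ligid, wall=np.asarray(wall, dtype=bool),
            kf_a=kf_a, kf_b=kf_b, anchor=anchor, mass=mass, mobile=mobile,
            bond_i=bi, bond_j=bj,
            bond_r0=np.asarray(self.bond_r0, dtype=float),
            bond_k=np.asarray(self.bond_k, dtype=float),
            ang_i=ai, ang_j=aj, ang_k=ak,
            ang_t0=np.asarray(self.angle_t0, dtype=float),
            ang_kt=np.asarray(self.angle_k, dtype=float),
            morph_ion=morph_ion, k_wall=self.k_wall, wall_radius=self.wall_radius,
            temperature=self.temperature, nb=self.nb,
        )
        ps.validate()
        return ps

    def with_coords(self, coords: np.ndarray) -> "ParticleSystem":
        return replace(self, coords=np.array(coords, dtype=float))

    def validate(self):
        q = self.total_charge
        ion = self.ion_atom()
        lig_q = sum(a.charge for a in self.atoms)
        assert abs(q - (ion.charge + lig_q)) < 1e-9
        if self.mode == "dual_restraint":
            n0 = np.sum(self.set_id == 0)
            n1 = np.sum(self.set_id == 1)
            if n0 != n1:
                raise ValueError("dual sets must have identical composition")


def _rotation_to(z_target: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z to the given unit direction."""
    z = np.asarray(z_target, dtype=float)
    z = z / np.linalg.norm(z)
    e = np.array([0.0, 0.0, 1.0])
    v = np.cross(e, z)
    c = float(np.dot(e, z))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    a = np.asarray(axis, float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _place_ligands(templates, directions, radius):
    """Place each template with its coordinating point at radius along its
    direction, carbon skeleton pointing outward."""
    coords, atoms, ligid, coord_mask = [], [], [], []
    bonds, br0, bk, angles, at0, akt = [], [], [], [], [], []
    offset = 0
    for li, (tpl, u) in enumerate(zip(templates, directions)):
        rot = _rotation_to(u)
        xyz = tpl.coords @ rot.T + np.asarray(u) * radius
        coords.append(xyz)
        atoms.extend(tpl.atoms)
        ligid.extend([li] * tpl.n_atoms)
        m = np.zeros(tpl.n_atoms, dtype=bool)
        m[list(tpl.coordinating)] = True
        coord_mask.append(m)
        for i, j, r0, k in tpl.bonds:
            bonds.append((i + offset, j + offset)); br0.append(r0); bk.append(k)
        for i, j, k3, t0, kt in tpl.angles:
            angles.append((i + offset, j + offset, k3 + offset)); at0.append(t0); akt.append(kt)
        offset += tpl.n_atoms
    return (
        np.vstack(coords), tuple(atoms), np.array(ligid), np.concatenate(coord_mask),
        np.array(bonds).reshape(-1, 2), np.array(br0), np.array(bk),
        np.array(angles).reshape(-1, 3), np.array(at0), np.array(akt),
    )


def _check_clashes(system: ParticleSystem, threshold: float = 0.5):
    """Reject construction if two *interacting* atoms are closer than the
    threshold (dual-topology partner sets are mutually non-interacting, and
    the ion sits at the origin)."""
    pos = np.vstack([np.zeros(3), system.coords])
    ligid = np.concatenate([[-1], system.ligand_id])
    setid = np.concatenate([[-1], system.set_id])
    n = len(pos)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if ligid[i] == ligid[j] and ligid[i] >= 0:
                continue
            if setid[i] >= 0 and setid[j] >= 0 and setid[i] != setid[j]:
                continue
            d = np.linalg.norm(pos[i] - pos[j])
            if d < threshold:
                raise ConstructionClashError(
                    f"atoms {i} and {j} are {d:.3f} A apart (< {threshold} A)"
                )


_PLACEMENT_RADIUS = 2.6  # initial coordination radius when no R_opt is known


def build_abstract_system(
    ion: str,
    n: int,
    R_opt: float | None = None,
    kf: float = 0.0,
    dual_sets: bool = False,
    *,
    anchors: AnchorGeometry | None = None,
    k_wall: float = C.K_WALL_DEFAULT,
    temperature: float = C.T_DEFAULT,
    ligand_kind: str = "formaldehyde_like",
    eight_fold: str = "square_antiprism",
) -> ParticleSystem:
    """Abstract n-ligand coordination cage around one fixed ion.

    With ``kf > 0`` every atom of the (first) ligand set is anchored at the
    geometry built from ``R_opt`` (the ion's own optimal radius, so the cage
    is strain-free); ``dual_sets=True`` adds the anchor-free partner set used
    by restraint morphs.
    """
    C.ion_type_name(ion)  # validates species
    if kf < 0:
        raise ValueError("kf must be >= 0")
    if kf > 0 and R_opt is None and anchors is None:
        raise ValueError("anchors require an optimal radius R_opt")
    if anchors is None:
        anchors = anchor_geometry(n, R_opt if R_opt is not None else _PLACEMENT_RADIUS,
                                  ion=ion, eight_fold=eight_fold)
    elif anchors.n != n:
        raise ValueError(f"anchor geometry is for n={anchors.n}, not n={n}")
    tpl = build_ligand_template(ligand_kind)
    directions = anchors.points / np.linalg.norm(anchors.points, axis=1, keepdims=True)
    templates = [tpl] * n
    (coords, atoms, ligid, cmask, bonds, br0, bk, angles, at0, akt) = _place_ligands(
        templates, directions, anchors.radius
    )
    set_id = np.zeros(len(atoms), dtype=int)
    anchor_pos = coords.copy()
    kf_arr = np.full(len(atoms), float(kf))
    if dual_sets:
        rot = _axis_rotation(np.array([1.0, 2.0, 3.0]), math.pi / 6.0)
        coords2 = coords @ rot.T
        coords = np.vstack([coords, coords2])
        atoms = atoms + atoms
        ligid = np.concatenate([ligid, ligid + n])
        cmask = np.concatenate([cmask, cmask])
        off = len(set_id)
        bonds = np.vstack([bonds, bonds + off])
        br0 = np.concatenate([br0, br0]); bk = np.concatenate([bk, bk])
        angles = np.vstack([angles, angles + off])
        at0 = np.concatenate([at0, at0]); akt = np.concatenate([akt, akt])
        set_id = np.concatenate([set_id, np.ones(off, dtype=int)])
        anchor_pos = np.vstack([anchor_pos, coords2])
        kf_arr = np.concatenate([kf_arr, np.zeros(off)])
    sys_ = ParticleSystem(
        ion_species=ion, coords=coords, atoms=atoms, ligand_id=ligid,
        set_id=set_id, coordinating=cmask,
        bonds=bonds, bond_r0=br0, bond_k=bk,
        angles=angles, angle_t0=at0, angle_k=akt,
        kf=kf_arr, kf_end=kf_arr.copy(), anchor_pos=anchor_pos,
        mode="dual_restraint" if dual_sets else "none",
        k_wall=k_wall, temperature=temperature,
        ligand_kinds=(ligand_kind,) * n, anchor_ion=anchors.ion,
    )
    _check_clashes(sys_)
    sys_.validate()
    return sys_


_FRAGMENT_OF = {"carbonyl": "backbone_carbonyl", "hydroxyl": "hydroxyl",
                "carboxylate": "carboxylate"}
_FRAGMENT_DISTANCE = {"carbonyl": 2.3, "hydroxyl": 2.4, "carboxylate": 2.5}


def build_site_model(site: str, ion: str, *, minimise_steps: int = 2000,
                     tol: float = 1e-4, temperature: float = C.T_DEFAULT,
                     k_wall: float = C.K_WALL_DEFAULT) -> ParticleSystem:
    """Transporter-site dipolar model with per-ion minimised anchor positions.

    The ligand composition follows the packaged site table; starting
    coordinates are idealised (coordinating atoms on polyhedral/packed
    directions at chemically sensible distances), then energy minimisation
    with the requested ion defines the anchor geometry — a synthetic stand-in
    for a crystal-structure extraction, keeping the package self-contained.
    """
    comps = C.site_compositions()
    if site not in comps:
        raise FixtureNotFoundError(
            f"unknown site {site!r}; available: {sorted(comps)}"
        )
    labels = comps[site]
    kinds = []
    for label in labels:
        frag = label.split(":")[1]
        if frag not in _FRAGMENT_OF:
            raise FixtureNotFoundError(f"{site}: unknown fragment in {label!r}")
        kinds.append(frag)
    n = len(labels)
    geom = anchor_geometry(min(max(n, 4), 8), 1.0, ion=ion)
    directions = geom.points[:n] / np.linalg.norm(geom.points[:n], axis=1, keepdims=True)
    templates = [build_ligand_template(_FRAGMENT_OF[k]) for k in kinds]
    coords, atoms, ligid, cmask = [], [], [], []
    bonds, br0, bk, angles, at0, akt = [], [], [], [], [], []
    offset = 0
    for li, (tpl, u, kind) in enumerate(zip(templates, directions, kinds)):
        rot = _rotation_to(u)
        xyz = tpl.coords @ rot.T + u * _FRAGMENT_DISTANCE[kind]
        coords.append(xyz)
        atoms.extend(tpl.atoms)
        ligid.extend([li] * tpl.n_atoms)
        m = np.zeros(tpl.n_atoms, dtype=bool)
        m[list(tpl.coordinating)] = True
        cmask.append(m)
        for i, j, r0, k in tpl.bonds:
            bonds.append((i + offset, j + offset)); br0.append(r0); bk.append(k)
        for i, j, k3, t0, kt in tpl.angles:
            angles.append((i + offset, j + offset, k3 + offset)); at0.append(t0); akt.append(kt)
        offset += tpl.n_atoms
    sys_ = ParticleSystem(
        ion_species=ion, coords=np.vstack(coords), atoms=tuple(atoms),
        ligand_id=np.array(ligid), set_id=np.zeros(offset, dtype=int),
        coordinating=np.concatenate(cmask),
        bonds=np.array(bonds).reshape(-1, 2), bond_r0=np.array(br0), bond_k=np.array(bk),
        angles=np.array(angles).reshape(-1, 3), angle_t0=np.array(at0), angle_k=np.array(akt),
        kf=np.zeros(offset), kf_end=np.zeros(offset),
        anchor_pos=np.vstack(coords), mode="none",
        k_wall=k_wall, temperature=temperature,
        ligand_kinds=tuple(kinds), anchor_ion=None,
    )
    _check_clashes(sys_)
    sys_ = minimise(sys_, max_steps=minimise_steps, tol=tol)
    # minimised coordinates define the (strain-free, per-ion) anchor geometry
    return replace(sys_, anchor_pos=sys_.coords.copy(), anchor_ion=ion)


# ---------------------------------------------------------------------------
# morph-system factories


def make_restraint_morph_system(base: ParticleSystem, kf: float) -> ParticleSystem:
    """Dual-topology restraint-morph system from an anchored single-set cage.

    lambda = 0: anchored set fully interacting; lambda = 1: the anchor-free
    partner set fully interacting.  Both endpoints have exactly n coordinating
    ligands.
    """
    if base.mode != "none":
        raise ValueError("base system must be a plain single-set cage")
    rot = _axis_rotation(np.array([1.0, 2.0, 3.0]), math.pi / 6.0)
    coords2 = base.coords @ rot.T
    off = base.coords.shape[0]
    n = base.n_ligands
    return replace(
        base,
        coords=np.vstack([base.coords, coords2]),
        atoms=base.atoms + base.atoms,
        ligand_id=np.concatenate([base.ligand_id, base.ligand_id + n]),
        set_id=np.concatenate([np.zeros(off, int), np.ones(off, int)]),
        coordinating=np.concatenate([base.coordinating, base.coordinating]),
        bonds=np.vstack([base.bonds, base.bonds + off]),
        bond_r0=np.concatenate([base.bond_r0, base.bond_r0]),
        bond_k=np.concatenate([base.bond_k, base.bond_k]),
        angles=np.vstack([base.angles, base.angles + off]),
        angle_t0=np.concatenate([base.angle_t0, base.angle_t0]),
        angle_k=np.concatenate([base.angle_k, base.angle_k]),
        kf=np.concatenate([np.full(off, float(kf)), np.zeros(off)]),
        kf_end=np.concatenate([np.full(off, float(kf)), np.zeros(off)]),
        anchor_pos=np.vstack([base.anchor_pos, coords2]),
        mode="dual_restraint",
    )


def make_ion_morph_system(base: ParticleSystem, ion_b: str) -> ParticleSystem:
    """Ion-identity morph (A -> B) on an unanchored, single-set cage."""
    from .errors import ProtocolError

    if np.any(base.kf > 0) or np.any(base.kf_end > 0):
        raise ProtocolError("ion morphs require an unanchored system (wall only)")
    if base.mode not in ("none",):
        raise ProtocolError("ion morphs use a single ligand set")
    C.ion_type_name(ion_b)
    return replace(base, mode="ion_morph", ion_species_b=ion_b)


def make_kf_morph_system(base: ParticleSystem, kf_start: float, kf_end: float) -> ParticleSystem:
    """Single-set morph interpolating the anchor force constant linearly in
    lambda.  Used by the analytic harmonic oracles (its free energy is the
    physical confinement free energy, with no dual-topology dummy offset)."""
    if base.mode != "none":
        raise ValueError("kf morph requires a plain single-set system")
    off = base.coords.shape[0]
    return replace(
        base,
        kf=np.full(off, float(kf_start)),
        kf_end=np.full(off, float(kf_end)),
        mode="kf_morph",
    )


# ---------------------------------------------------------------------------
# toys


def toy_anchored_atom(kf: float, *, mass: float = 15.9994,
                      temperature: float = C.T_DEFAULT) -> ParticleSystem:
    """A single chargeless, dispersionless atom in an isotropic harmonic well.

    The analytic oracle system: positional RMS fluctuation sqrt(3 kB T / kf),
    mean potential energy (3/2) kB T independent of kf, and closed-form
    confinement free energies.
    """
    atom = Atom("TOY", "O", 0.0, 0.0, 1.0, mass)
    return ParticleSystem(
        ion_species="Na",
        coords=np.zeros((1, 3)),
        atoms=(atom,),
        ligand_id=np.array([0]),
        set_id=np.array([0]),
        coordinating=np.array([False]),
        bonds=np.empty((0, 2), int), bond_r0=np.empty(0), bond_k=np.empty(0),
        angles=np.empty((0, 3), int), angle_t0=np.empty(0), angle_k=np.empty(0),
        kf=np.array([float(kf)]), kf_end=np.array([float(kf)]),
        anchor_pos=np.zeros((1, 3)),
        mode="none", temperature=temperature,
    )


def toy_ideal_gas(n_atoms: int = 4, *, kf: float = 0.0, mass: float = 15.9994,
                  temperature: float = C.T_DEFAULT) -> ParticleSystem:
    """``n_atoms`` mutually non-interacting, chargeless, dispersionless atoms,
    each confined by the 3.5 A wall and (optionally) anchored at the origin.

    The cleanest analytic oracle: the configuration integral factorises into
    identical radial one-particle integrals, so confinement free energies
    follow from 1-D quadrature and the mean anchor energy from equipartition.
    """
    atom = Atom("TOY", "O", 0.0, 0.0, 1.0, mass)
    n = int(n_atoms)
    return ParticleSystem(
        ion_species="Na",
        coords=np.zeros((n, 3)),
        atoms=(atom,) * n,
        ligand_id=np.arange(n),
        set_id=np.zeros(n, dtype=int),
        coordinating=np.ones(n, dtype=bool),
        bonds=np.empty((0, 2), int), bond_r0=np.empty(0), bond_k=np.empty(0),
        angles=np.empty((0, 3), int), angle_t0=np.empty(0), angle_k=np.empty(0),
        kf=np.full(n, float(kf)), kf_end=np.full(n, float(kf)),
        anchor_pos=np.zeros((n, 3)),
        mode="none", temperature=temperature,
    )


def toy_ideal_cage(n: int = 1, *, kf: float = 0.0, R: float = 2.3,
                   temperature: float = C.T_DEFAULT) -> ParticleSystem:
    """Non-interacting cage: formaldehyde-shaped ligands with charges and
    dispersion zeroed, keeping bonds, wall, and anchors.  Free energies,
    enthalpies, and entropies follow from one-particle configuration
    integrals."""
    base = build_abstract_system("Na", max(n, 4), R_opt=R, kf=kf,
                                 temperature=temperature)
    keep = base.ligand_id < n
    atoms = tuple(
        Atom(a.type_name, a.element, 0.0, 0.0, a.sigma, a.mass)
        for a, k in zip(base.atoms, keep) if k
    )
    idx = np.where(keep)[0]
    remap = {int(o): i for i, o in enumerate(idx)}
    bsel = np.all(np.isin(base.bonds, idx), axis=1)
    asel = np.all(np.isin(base.angles, idx), axis=1)
    bonds = np.array([[remap[int(i)], remap[int(j)]] for i, j in base.bonds[bsel]]).reshape(-1, 2)
    angs = np.array([[remap[int(i)], remap[int(j)], remap[int(k)]]
                     for i, j, k in base.angles[asel]]).reshape(-1, 3)
    return replace(
        base,
        coords=base.coords[keep], atoms=atoms,
        ligand_id=base.ligand_id[keep], set_id=base.set_id[keep],
        coordinating=base.coordinating[keep],
        bonds=bonds, bond_r0=base.bond_r0[bsel], bond_k=base.bond_k[bsel],
        angles=angs, angle_t0=base.angle_t0[asel], angle_k=base.angle_k[asel],
        kf=base.kf[keep], kf_end=base.kf_end[keep], anchor_pos=base.anchor_pos[keep],
        ligand_kinds=base.ligand_kinds[:n],
    )


# ---------------------------------------------------------------------------
# minimisation


def minimise(system: ParticleSystem, max_steps: int = 1000,
             tol: float = 1e-4, lam: float = 0.0) -> ParticleSystem:
    """Energy-minimise ligand coordinates (L-BFGS on the analytic gradient).

    Stops when the largest force component drops below ``tol`` (kcal/mol/A)
    or after ``max_steps`` evaluations.  The ion stays fixed at the origin.
    """
    packed = system.packed()
    args = packed.static_args()
    n_ion = 1

    def fun(x):
        pos = np.vstack([np.zeros(3), x.reshape(-1, 3)])
        comps, f = _energy_forces(pos, lam, *args)
        e = float(np.sum(comps))
        if not np.isfinite(e):
            raise DivergenceError("non-finite energy during minimisation")
        return e, -f[n_ion:].ravel()

    res = _scipy_minimize(
        fun, system.coords.ravel().copy(), jac=True, method="L-BFGS-B",
        options={"maxiter": max_steps, "gtol": tol * 0.1, "ftol": 1e-14},
    )
    out = system.with_coords(res.x.reshape(-1, 3))
    return out
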