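"""Post-processing: radial distribution functions and optimal radii,
enthalpy/entropy decomposition, RMS fluctuations, and occupancy-grid sampled
volumes.

The entropic mechanism is read out of these quantities: the optimal
ion-oxygen radius (first RDF peak) defines strain-free anchor placement; the
endpoint-energy decomposition splits the exchange free energy into dH and
-T*dS; the RMSF curve maps anchor stiffness kf onto physically observable
positional fluctuations; and the sampled volume quantifies the
configurational space the ligands lose when their fluctuations are reduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from . import constants as C
from .errors import CycleInconsistencyError, SelectionError
from .sampler import Trajectory

__all__ = [
    "RDFProfile",
    "ThermoDecomposition",
    "OccupancyGrid",
    "compute_rdf",
    "first_peak",
    "decompose",
    "rms_fluctuation",
    "occupancy_volume",
    "occupancy_grid",
    "coordinating_oxygen_indices",
]


def coordinating_oxygen_indices(traj: Trajectory, active_set_only: bool = True) -> np.ndarray:
    """Packed-atom indices of the walled (coordinating) oxygens."""
    packed = traj.packed
    sel = np.where(packed.wall)[0]
    if active_set_only:
        sel = sel[packed.group[sel] != 2] if hasattr(packed, "group") else sel
    if sel.size == 0:
        raise SelectionError("system has no coordinating oxygens")
    return sel


@dataclass(frozen=True)
class RDFProfile:
    """Ion-oxygen radial distribution with its first-peak location."""

    bin_centers: np.ndarray
    g: np.ndarray
    first_peak_r: float
    sample_count: int

    def validate(self):
        assert np.all(self.g >= 0)
        assert self.bin_centers[0] <= self.first_peak_r <= self.bin_centers[-1]


def first_peak(bin_centers: np.ndarray, g: np.ndarray, threshold: float = 1.0) -> float:
    """First local maximum of the (3-bin smoothed) RDF above the threshold.

    Deliberately the *first* peak: the optimum radius must not drift to the
    second coordination shell that crowded cages develop.
    """
    gs = np.convolve(g, np.ones(3) / 3.0, mode="same")
    for i in range(1, len(gs) - 1):
        if gs[i] >= gs[i - 1] and gs[i] >= gs[i + 1] and gs[i] > threshold:
            return float(bin_centers[i])
    i = int(np.argmax(gs))
    return float(bin_centers[i])


def compute_rdf(traj: Trajectory, atoms=None, bin_width: float = 0.02,
                r_max: float | None = None) -> RDFProfile:
    """Ion-oxygen RDF normalised by shell volume and mean selection density."""
    if traj.n_frames < 100:
        raise ValueError("need at least 100 frames for a stable RDF")
    if atoms is None:
        atoms = coordinating_oxygen_indices(traj)
    atoms = np.asarray(atoms, dtype=int)
    if atoms.size == 0:
        raise SelectionError("empty atom selection for RDF")
    d = np.linalg.norm(traj.frames[:, atoms, :], axis=2).ravel()
    if r_max is None:
        r_max = float(np.max(d)) + bin_width
    nbins = max(int(math.ceil(r_max / bin_width)), 4)
    counts, edges = np.histogram(d, bins=nbins, range=(0.0, nbins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * math.pi * centers**2 * bin_width
    rho = atoms.size / ((4.0 / 3.0) * math.pi * (nbins * bin_width) ** 3)
    g = counts / (traj.n_frames * shell * rho)
    peak = first_peak(centers, g)
    prof = RDFProfile(bin_centers=centers, g=g, first_peak_r=peak,
                      sample_count=int(d.size))
    prof.validate()
    return prof


@dataclass(frozen=True)
class ThermoDecomposition:
    """(dG, dH, -T dS) triple at one anchor stiffness kf, kcal/mol."""

    kf: float
    dG: float
    dH: float
    T: float = C.T_DEFAULT

    @property
    def minus_TdS(self) -> float:
        return self.dG - self.dH

    def validate(self):
        assert abs(self.dG - (self.dH + self.minus_TdS)) < 1e-9


def decompose(cycles, endpoint_dH=None, T: float = C.T_DEFAULT) -> list[ThermoDecomposition]:
    """Enthalpy/entropy decomposition of the fluctuation-driven selectivity.

    ``cycles`` is a sequence of CycleResult at increasing kf.  dH is
    assembled from endpoint mean potential energies with the same cycle
    arithmetic as dG (carried on each cycle as ``ddH_constraint``), or can be
    supplied explicitly per kf; -T dS is the arithmetic remainder dG - dH.
    """
    out = []
    for i, cyc in enumerate(cycles):
        if endpoint_dH is not None:
            dh = float(endpoint_dH[i])
        else:
            dh = cyc.ddH_constraint
        if not math.isfinite(dh):
            raise CycleInconsistencyError(
                f"cycle at kf={cyc.kf} carries no endpoint enthalpy data"
            )
        td = ThermoDecomposition(kf=cyc.kf, dG=cyc.ddG_RLF, dH=dh, T=T)
        td.validate()
        out.append(td)
    return out


def rms_fluctuation(traj: Trajectory, atoms=None):
    """RMS deviation of each selected atom from its trajectory-mean position.

    Returns (per_atom, pooled) in Angstrom; pooled is the RMS over the
    selection, the x-axis that maps kf onto observable fluctuation size.
    """
    if traj.n_frames < 2:
        raise ValueError("fluctuations are undefined for a single frame")
    if traj.n_frames < 100:
        raise ValueError("need at least 100 frames for converged fluctuations")
    if atoms is None:
        atoms = np.where(traj.packed.mobile)[0]
    atoms = np.asarray(atoms, dtype=int)
    if atoms.size == 0:
        raise SelectionError("empty atom selection for RMSF")
    x = traj.frames[:, atoms, :]
    mean = x.mean(axis=0)
    msd = np.mean(np.sum((x - mean) ** 2, axis=2), axis=0)
    per_atom = np.sqrt(msd)
    pooled = float(np.sqrt(np.mean(msd)))
    return per_atom, pooled


# ---------------------------------------------------------------------------
# occupancy volumes


@njit(cache=True)
def _mark_occupancy(frames, radii, origin, spacing, counts):
    nx, ny, nz = counts.shape
    nf = frames.shape[0]
    na = frames.shape[1]
    frame_hits = np.zeros((nx, ny, nz), dtype=np.uint8)
    for f in range(nf):
        frame_hits[:, :, :] = 0
        for a in range(na):
            r = radii[a]
            r2 = r * r
            cx = frames[f, a, 0]
            cy = frames[f, a, 1]
            cz = frames[f, a, 2]
            i0 = max(int((cx - r - origin[0]) / spacing), 0)
            i1 = min(int((cx + r - origin[0]) / spacing) + 1, nx - 1)
            j0 = max(int((cy - r - origin[1]) / spacing), 0)
            j1 = min(int((cy + r - origin[1]) / spacing) + 1, ny - 1)
            k0 = max(int((cz - r - origin[2]) / spacing), 0)
            k1 = min(int((cz + r - origin[2]) / spacing) + 1, nz - 1)
            for i in range(i0, i1 + 1):
                x = origin[0] + (i + 0.5) * spacing - cx
                for j in range(j0, j1 + 1):
                    y = origin[1] + (j + 0.5) * spacing - cy
                    xy2 = x * x + y * y
                    if xy2 > r2:
                        continue
                    for k in range(k0, k1 + 1):
                        z = origin[2] + (k + 0.5) * spacing - cz
                        if xy2 + z * z <= r2:
                            frame_hits[i, j, k] = 1
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    counts[i, j, k] += frame_hits[i, j, k]


@dataclass
class OccupancyGrid:
    """Voxelised union-of-spheres occupancy accumulated over frames."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray          # voxels covered per frame count
    n_frames: int

    @property
    def fraction(self) -> np.ndarray:
        return self.counts / max(self.n_frames, 1)

    def volume(self, isovalue: float = 1.0, mode: str = "cumulative") -> float:
        """Volume (A^3) of voxels passing the isovalue under the chosen mode.

        ``cumulative``: every voxel ever occupied counts once (the default;
        the configurational-space reading).  ``frame_fraction``: voxels whose
        occupied-frame fraction reaches the isovalue (VolMap-style
        averaging).
        """
        if mode == "cumulative":
            n = int(np.count_nonzero(self.counts))
        elif mode == "frame_fraction":
            n = int(np.count_nonzero(self.fraction >= isovalue))
        else:
            raise ValueError(f"unknown occupancy mode {mode!r}")
        return n * self.spacing**3


def occupancy_grid(traj: Trajectory, atoms=None, spacing: float = 0.1,
                   radii=None, padding: float = 1.0) -> OccupancyGrid:
    """Accumulate the union-of-spheres occupancy of selected atoms."""
    if atoms is None:
        atoms = coordinating_oxygen_indices(traj, active_set_only=False)
    atoms = np.asarray(atoms, dtype=int)
    if atoms.size == 0:
        raise SelectionError("empty atom selection for occupancy")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    table = C.vdw_radii()
    packed = traj.packed
    if radii is None:
        elements = _packed_elements(traj)
        radii = np.array([table[elements[a]] for a in atoms])
    else:
        radii = np.asarray(radii, dtype=float)
    x = traj.frames[:, atoms, :]
    rmax = float(np.max(radii))
    lo = x.min(axis=(0, 1)) - rmax - padding
    hi = x.max(axis=(0, 1)) + rmax + padding
    nvox = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    counts = np.zeros(tuple(nvox), dtype=np.int32)
    _mark_occupancy(np.ascontiguousarray(x), radii, lo.astype(float),
                    float(spacing), counts)
    del packed
    return OccupancyGrid(origin=lo, spacing=float(spacing), counts=counts,
                         n_frames=traj.n_frames)


def _packed_elements(traj: Trajectory):
    """Element symbols per packed atom, inferred from masses (the packed view
    keeps no element strings)."""
    known = [("H", 1.008), ("Li", 6.941), ("C", 12.011), ("O", 15.9994),
             ("Na", 22.98977), ("K", 39.0983)]
    out = []
    for m in traj.packed.mass:
        sym = min(known, key=lambda kv: abs(kv[1] - m))[0]
        out.append(sym)
    return out


def occupancy_volume(traj: Trajectory, atoms=None, spacing: float = 0.1,
                     isovalue: float = 1.0, mode: str = "cumulative",
                     radii=None) -> float:
    """Sampled volume (A^3) of the selected atoms over the trajectory."""
    if traj.n_frames == 0:
        return 0.0
    grid = occupancy_grid(traj, atoms=atoms, spacing=spacing, radii=radii)
    return grid.volume(isovalue=isovalue, mode=mode)
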