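"""Physical constants, unit conversions, and packaged parameter tables.

Internal units: length in Angstrom, energy in kcal/mol, time in fs, mass in
amu, charge in elementary charges, temperature in K.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd
import yaml

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: Coulomb constant, kcal*A/(mol*e^2) (CODATA-derived).
COULOMB = 332.063713

#: (kcal/mol/A) / amu  ->  A/fs^2. Also converts (amu*(A/fs)^2) -> kcal/mol
#: when divided out of kinetic energy.
ACC_CONV = 4.184e-4

#: Default simulation temperature, K.
T_DEFAULT = 310.0

#: Default Langevin timestep, fs.
DT_DEFAULT = 1.0

#: Default Langevin friction, 1/fs (5 ps^-1).
FRICTION_DEFAULT = 0.005

#: Flat-bottom spherical wall radius on coordinating oxygens, Angstrom.
WALL_RADIUS = 3.5

#: Default wall force constant ("very large"), kcal/mol/A^2.
K_WALL_DEFAULT = 100.0


def _data_path(name: str):
    return resources.files("rlfsim.data").joinpath(name)


@functools.lru_cache(maxsize=None)
def atom_params() -> pd.DataFrame:
    """Nonbonded parameter table (ions and ligand atom types), indexed by name."""
    with resources.as_file(_data_path("parameters.csv")) as p:
        # keep_default_na: "NA" is the sodium type name, not a missing value
        df = pd.read_csv(p, comment="#", keep_default_na=False)
    num = ["charge_e", "epsilon_kcal_mol", "sigma_A", "mass_amu"]
    df[num] = df[num].astype(float)
    return df.set_index("name")


@functools.lru_cache(maxsize=None)
def bonded_params() -> pd.DataFrame:
    with resources.as_file(_data_path("bonded.csv")) as p:
        return pd.read_csv(p, comment="#")


@functools.lru_cache(maxsize=None)
def hydration_free_energies() -> dict[str, float]:
    """Single-ion hydration free energies, kcal/mol, keyed by species."""
    with resources.as_file(_data_path("hydration.csv")) as p:
        df = pd.read_csv(p, comment="#")
    return dict(zip(df["species"], df["dG_hydr_kcal_mol"]))


def ddG_hydration(ion_a: str, ion_b: str) -> float:
    """Bulk-leg constant: dG_hydr(B) - dG_hydr(A), kcal/mol."""
    g = hydration_free_energies()
    return g[ion_b] - g[ion_a]


@functools.lru_cache(maxsize=None)
def vdw_radii() -> dict[str, float]:
    with resources.as_file(_data_path("vdw_radii.csv")) as p:
        df = pd.read_csv(p, comment="#")
    return dict(zip(df["element"], df["radius_A"]))


@functools.lru_cache(maxsize=None)
def site_compositions() -> dict[str, list[str]]:
    """Transporter-site ligand compositions (residue:fragment labels)."""
    with resources.as_file(_data_path("site_compositions.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


ION_SPECIES = ("Li", "Na", "K")

_ION_TYPE = {"Li": "LI", "Na": "NA", "K": "K"}


def ion_type_name(species: str) -> str:
    try:
        return _ION_TYPE[species]
    except KeyError:
        raise ValueError(
            f"unknown ion species {species!r}; expected one of {ION_SPECIES}"
        ) from None
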