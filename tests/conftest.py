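import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def na6_cage():
    from rlfsim import build_abstract_system

    return build_abstract_system("Na", 6, R_opt=2.35)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_bare_ion(species="Na"):
    """A ParticleSystem containing only the fixed central ion."""
    import numpy as np

    from rlfsim.systems import ParticleSystem

    return ParticleSystem(
        ion_species=species,
        coords=np.zeros((0, 3)),
        atoms=(),
        ligand_id=np.empty(0, dtype=int),
        set_id=np.empty(0, dtype=int),
        coordinating=np.empty(0, dtype=bool),
        bonds=np.empty((0, 2), int), bond_r0=np.empty(0), bond_k=np.empty(0),
        angles=np.empty((0, 3), int), angle_t0=np.empty(0), angle_k=np.empty(0),
        kf=np.empty(0), kf_end=np.empty(0), anchor_pos=np.empty((0, 3)),
        mode="none",
    )
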