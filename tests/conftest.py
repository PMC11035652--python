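import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True,
                               deadline=None)
_hyp_settings.load_profile("deterministic")

from condnet.forcefield import (AngleClass, BeadType, BondClass,
                                DihedralClass, ForceField, QuadDihedralClass,
                                lj_forcefield)
from condnet.topology import Frame, MoleculeTemplate, Topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def lj_ff():
    return lj_forcefield()


@pytest.fixture
def bonded_ff():
    """Small multi-type force field exercising every interaction term."""
    beads = {
        "A": BeadType("A", "charged", sigma=1.0, epsilon=0.8, charge=-1,
                      mass=2.0, elec_cutoff=6.0),
        "B": BeadType("B", "charged", sigma=1.2, epsilon=0.5, charge=1,
                      mass=1.5, elec_cutoff=4.0),
        "C": BeadType("C", "small", sigma=0.9, epsilon=0.3, charge=0,
                      mass=1.0),
    }
    return ForceField(
        bead_types=beads, lj_cutoff_factor=2.5, dielectric=2.0, kappa=0.3,
        coulomb_constant=1.0, elec_cutoff_default=5.0,
        bonds={"bb": BondClass(K=7.0, b0=1.1)},
        angles={"aa": AngleClass(K=3.0, theta0=1.9)},
        dihedrals={"dd": DihedralClass(K=(1.2, 0.7, 0.4),
                                       phi=(0.3, -0.5, 1.1))},
        quad_dihedrals={"qq": QuadDihedralClass(K=2.0, phi0=0.4)},
        units="reduced",
    )


@pytest.fixture
def chain_topology():
    """Two 4-bead charged chains plus two free beads (all terms present)."""
    chain = MoleculeTemplate(
        label="chain",
        bead_types=("A", "B", "C", "A"),
        regions=("head", "mid", "mid", "tail"),
        charges=(-1, 1, 0, -1),
        bonds=((0, 1, "bb"), (1, 2, "bb"), (2, 3, "bb")),
        angles=((0, 1, 2, "aa"), (1, 2, 3, "aa")),
        dihedrals=((0, 1, 2, 3, "dd"),),
        quad_dihedrals=((0, 1, 2, 3, "qq"),),
    )
    free = MoleculeTemplate(label="free", bead_types=("C",),
                            regions=("free",), charges=(0,))
    return Topology([(chain, 2), (free, 2)])


@pytest.fixture
def chain_frame(chain_topology, rng):
    box = np.array([8.0, 8.0, 8.0])
    coords = rng.random((chain_topology.n_beads, 3)) * box
    # keep bonded neighbors at sane separations
    for m in range(2):
        base = m * 4
        for k in range(1, 4):
            step = rng.standard_normal(3)
            coords[base + k] = coords[base + k - 1] + \
                1.1 * step / np.linalg.norm(step)
    return Frame.from_unwrapped(coords, box)


def random_lj_frame(rng, n, box_edge, min_sep=0.8):
    """Random frame with a floor on pair separations (finite LJ energies)."""
    from condnet.simulate import initialize_configuration
    from condnet.topology import single_type_topology

    topo = single_type_topology(n)
    return topo, initialize_configuration(
        topo, [box_edge] * 3, "random_nonoverlapping",
        seed=int(rng.integers(2**31)), min_sep=min_sep)
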