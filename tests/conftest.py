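import numpy as np
import pytest

from ionvol import (SALTS, SolvationSnapshot, ThermalVolumeModel,
                    default_context, study_context)


@pytest.fixture(scope="session")
def ctx():
    return default_context()


@pytest.fixture(scope="session")
def sctx():
    """Context with the study-consistent Debye-Hückel slope (Av(25)=1.65)."""
    return study_context()


@pytest.fixture(scope="session")
def nacl():
    return SALTS["NaCl"]


@pytest.fixture(scope="session")
def nacl_truth():
    return ThermalVolumeModel(V_ref=16.43, alpha=87e-3, beta=-2.6e-3)


def make_snapshot(waters, box_edge=25.0, ion=(0.0, 0.0, 0.0)):
    """Build a snapshot from a list of (O, H1, H2) coordinate triplets."""
    O = np.array([w[0] for w in waters], dtype=float).reshape(-1, 3)
    H1 = np.array([w[1] for w in waters], dtype=float).reshape(-1, 3)
    H2 = np.array([w[2] for w in waters], dtype=float).reshape(-1, 3)
    return SolvationSnapshot(box_edge=box_edge,
                             ion_position=np.asarray(ion, dtype=float),
                             O=O, H1=H1, H2=H2)


@pytest.fixture
def collinear_water_snapshot():
    # O at 3 Å from the ion on x; hydrogens beyond it so Q=(3.586,0,0):
    # O->ion and O->Q are antiparallel, theta = 180 deg.
    return make_snapshot(
        [((3.0, 0, 0), (3.586, 0.757, 0), (3.586, -0.757, 0))])
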