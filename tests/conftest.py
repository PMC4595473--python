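import numpy as np
import pytest

from ipr_gating import FluxParams, LigandCondition, OccupancyParams


@pytest.fixture(scope="session")
def wt():
    return OccupancyParams.wild_type(), FluxParams.wild_type()


@pytest.fixture(scope="session")
def mutant():
    return OccupancyParams.m146l(), FluxParams.m146l()


@pytest.fixture(scope="session")
def optimal_lig():
    """The fitting condition of the study: 1 uM Ca2+, 100 nM IP3."""
    return LigandCondition(1.0, 0.1)


@pytest.fixture(scope="session")
def ligand_grid():
    """Coarse (Ca, IP3) grid spanning the physiological range, in uM."""
    cas = np.geomspace(0.01, 10.0, 7)
    ip3s = np.geomspace(0.001, 10.0, 7)
    return [LigandCondition(float(c), float(i)) for c in cas for i in ip3s]
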