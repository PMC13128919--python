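import numpy as np
import pytest

from lobehf import ScreeningConfig, SCFConfig, scf_solve
from lobehf.fixtures import make_named_small, make_water_cluster
from lobehf.reference import reference_rhf


@pytest.fixture(scope="session")
def h2():
    return make_named_small("H2")


@pytest.fixture(scope="session")
def water():
    return make_named_small("H2O")


@pytest.fixture(scope="session")
def water_trimer():
    return make_water_cluster(3, seed=11)


@pytest.fixture(scope="session")
def h2_state(h2):
    return scf_solve(h2, screening_cfg=ScreeningConfig.off())


@pytest.fixture(scope="session")
def water_state(water):
    return scf_solve(water, screening_cfg=ScreeningConfig.off())


@pytest.fixture(scope="session")
def h2_reference(h2):
    return reference_rhf(h2)


@pytest.fixture(scope="session")
def water_reference(water):
    return reference_rhf(water)


@pytest.fixture(scope="session")
def tight_scf():
    return SCFConfig(rmsd_threshold=1e-9)
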