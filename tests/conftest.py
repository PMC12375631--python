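import numpy as np
import pytest

from cordlevel.phantom import AcquisitionSpec, CohortConfig, build_anatomy


@pytest.fixture(scope="session")
def desk_config() -> CohortConfig:
    """Desk-scale cohort configuration (default reduced grid)."""
    return CohortConfig(seed=1234)


@pytest.fixture(scope="session")
def template_anatomy(desk_config):
    """Noiseless template anatomy (no subject geometry variation, no lesion)."""
    return build_anatomy(desk_config.grid, desk_config, rng=None)


@pytest.fixture(scope="session")
def ms_anatomy(desk_config):
    """One seeded patient anatomy with lesions."""
    return build_anatomy(desk_config.grid, desk_config,
                         rng=np.random.default_rng(7), group="pwRRMS")


@pytest.fixture(scope="session")
def noiseless_acq() -> AcquisitionSpec:
    return AcquisitionSpec(snr=None)
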