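import numpy as np
import pytest

import prairiecarbon as pc


@pytest.fixture(scope="session")
def baseline_config() -> pc.SyntheticConfig:
    return pc.SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def baseline_climate(baseline_config) -> pc.ClimateSeries:
    return pc.make_climate(baseline_config)


@pytest.fixture(scope="session")
def default_mgmt() -> pc.Management:
    return pc.Management(stover_removal_rate=0.5)


@pytest.fixture()
def quiet_climate() -> pc.ClimateSeries:
    """Noise-free baseline climate over 10 years."""
    cfg = pc.SyntheticConfig(
        seed=0, start_year=2001, end_year=2010,
        temp_noise_sd=0.0, precip_noise_cv=0.0, climate_track="BASELINE",
    )
    return pc.make_climate(cfg)


@pytest.fixture(scope="session")
def single_pool_params() -> pc.DecompositionParams:
    """Decomposition config isolating one active pool with full respiration."""
    return pc.DecompositionParams(
        k_month={"structural": 0.0, "metabolic": 0.0, "active": 0.01,
                 "slow": 0.0, "passive": 0.0},
        respiration_fraction={"structural": 1.0, "metabolic": 1.0,
                              "active": 1.0, "slow": 1.0, "passive": 1.0},
    )


def make_single_pool_state(c0: float = 2.0) -> pc.CarbonState:
    return pc.CarbonState(
        litter_structural=0.0,
        litter_metabolic=0.0,
        som=np.array([[c0, 0.0, 0.0]]),
        layer_thickness_m=np.array([0.2]),
    )
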