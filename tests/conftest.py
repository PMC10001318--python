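import dataclasses

import pytest

from bnctsim import ScenarioConfig, build_grid
from bnctsim.config import BNCTDoseConfig, EBRTConfig, GridConfig


@pytest.fixture
def toy_grid():
    """90 x 90 grid of 1 mm cells: full 90 mm extent at coarse resolution."""
    return build_grid(90, 90, 1000.0)


@pytest.fixture
def small_grid():
    """50 x 50 grid of 200 um cells (10 mm extent) for loop-oracle tests."""
    return build_grid(50, 50, 200.0)


@pytest.fixture
def fast_config():
    """Reduced-resolution scenario config that runs in well under a second."""
    return ScenarioConfig(
        master_seed=7,
        grid=GridConfig(n_x=90, n_y=90, cell_size_um=1000.0),
        bnct_dose=BNCTDoseConfig(n_runs=3),
        ebrt=EBRTConfig(n_runs=3),
    )


@pytest.fixture
def homogeneous_config(fast_config):
    """Noise-free, homogeneous-radiosensitivity variant of fast_config."""
    return dataclasses.replace(
        fast_config,
        bnct_dose=dataclasses.replace(fast_config.bnct_dose, noise_rel=0.0),
        ebrt=dataclasses.replace(fast_config.ebrt, noise_rel=0.0),
        radiosensitivity=dataclasses.replace(
            fast_config.radiosensitivity, alpha_sd=0.0, beta_sd=0.0
        ),
    )
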