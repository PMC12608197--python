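import numpy as np
import pytest

import leafspec as ls
from leafspec.grid import WavelengthGrid


@pytest.fixture(scope="session")
def window_grid():
    return ls.modeling_window_grid()


@pytest.fixture(scope="session")
def small_grid():
    """Compact 60-channel grid for fast unit tests."""
    return WavelengthGrid(500.0 + 2.0 * np.arange(60))


@pytest.fixture(scope="session")
def small_fixture(small_grid):
    """60-sample, 60-channel table with one planted band at 540 nm."""
    cfg = ls.SimulationConfig(
        seed=7,
        n_samples=60,
        planted_bands=((540.0, 6.0, 0.05),),
        noise_sd=0.01,
        drift_sd=0.005,
        grid=small_grid,
    )
    table, resp = ls.simulate_spectra(cfg)
    return cfg, table, resp


@pytest.fixture(scope="session")
def nitrogen_fixture(window_grid):
    """Default-condition nitrogen table on the full 646-channel window."""
    cfg = ls.SimulationConfig(seed=11, n_samples=200)
    table, resp = ls.simulate_spectra(cfg)
    return cfg, table, resp
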