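import numpy as np
import pytest
from hypothesis import settings

import shearwater as sw

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noiseless_bird():
    """One Menorcan bird-year with noise-free light and immersion traces."""
    sch = sw.simulate_schedule("Menorca", 2012, seed=5)
    light = sw.simulate_light(sch, twilight_jitter_sd_min=0.0,
                              shading_events_per_day=0.0, seed=1)
    imm = sw.simulate_immersion(sch, seed=2)
    return sch, light, imm


@pytest.fixture(scope="session")
def gaussian_kde_10k():
    """Standard bivariate normal sample with plug-in KDE on a fine grid."""
    rng = np.random.default_rng(42)
    x = rng.normal(size=(10000, 2))
    h = sw.plugin_bandwidth(x)
    grid = sw.kernel_density(x, h, cell_km=0.08)
    return x, h, grid
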