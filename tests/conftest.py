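import numpy as np
import pytest

from habcast import GridSpec, SyntheticConfig, simulate_hindcasts, simulate_truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_grid():
    """Coarse 8 x 10 cell grid at 2-degree resolution."""
    return GridSpec.regular(46.0, 62.0, -28.0, -8.0, step=2.0)


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale synthetic world: 10 x 12 cells, 34 years, 3 models x 2 members."""
    return SyntheticConfig(
        lat_min=50.0, lat_max=60.0, lon_min=-24.0, lon_max=-12.0, step=1.0,
        years=(1980, 2018), n_models=3, members_per_model=2,
        leads=tuple(range(1, 6)), seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    truth = simulate_truth(small_cfg)
    hind = simulate_hindcasts(truth, small_cfg)
    return truth, hind
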