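import numpy as np
import pytest

import prefbandit as pb
from prefbandit.inference import SamplerConfig


@pytest.fixture(scope="session")
def small_study():
    """An 8-participant synthetic study at default conditions (seeded)."""
    return pb.generate_study(8, "RL2", pb.ParamSampler(), 123)


@pytest.fixture(scope="session")
def light_sampler():
    """Short chains for tests that only need rough posterior summaries."""
    return SamplerConfig(n_chains=2, n_draws=1000, n_warmup=500)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
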