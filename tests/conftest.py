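import numpy as np
import pytest
from hypothesis import settings

from devallometry import synthgen

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return synthgen.GeneratorConfig(n_species=60, n_orders=5, seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthgen.generate_study(small_config)


@pytest.fixture(scope="session")
def study_paths(small_study, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("synth")
    return small_study.write_inputs(outdir)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
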