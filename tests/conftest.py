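import numpy as np
import pytest

from homolot import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config():
    return sd.SyntheticConfig(seed=11, n_model_queries=30, n_families=10, n_decoy_queries=4)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return sd.make_homolog_corpus(small_config)


@pytest.fixture(scope="session")
def small_hhr(small_config, small_corpus):
    return sd.make_hhr_tables(small_corpus, small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
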