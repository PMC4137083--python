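import numpy as np
import pytest

from ccci import SimConfig
from ccci.synthetic import (
    generate_evidence,
    generate_localization_experiments,
    generate_universe,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_genes=60, community_sizes=(8, 10), n_terms=15, n_tfs=4,
                     seed=7)


@pytest.fixture(scope="session")
def small_universe(small_cfg):
    rng = np.random.default_rng(small_cfg.seed)
    universe, truth = generate_universe(small_cfg, rng)
    return universe, truth


@pytest.fixture(scope="session")
def small_evidence(small_cfg, small_universe):
    universe, truth = small_universe
    return generate_evidence(universe, truth, small_cfg,
                             np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_experiments(small_cfg, small_universe):
    universe, truth = small_universe
    return generate_localization_experiments(universe, truth, small_cfg,
                                             np.random.default_rng(12))
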