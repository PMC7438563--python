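import numpy as np
import pytest

from gocsim.genome import GenomeMap
from gocsim.scheme import BaseConfig, initialize_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_base(**kwargs) -> BaseConfig:
    """A miniature study base: 3 short chromosomes, small panels."""
    defaults = dict(
        genome_map=GenomeMap(n_chromosomes=3, bp_per_chromosome=30e6),
        n_founders=120,
        n_offspring=120,
        panel_sizes={"M": 120, "Q": 120, "N": 120, "D": 120},
        n_initial_parents_per_sex=12,
    )
    defaults.update(kwargs)
    return BaseConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_shared():
    """A shared tiny replicate reused by read-only tests."""
    return initialize_replicate(tiny_base(), 2024)
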