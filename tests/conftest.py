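import numpy as np
import pytest

from hnsomatic.synthetic import CohortConfig, generate_panel


@pytest.fixture(scope="session")
def small_panel():
    """20-gene panel carrying all the named recurrent genes."""
    return generate_panel(20, 5, seed=11)


@pytest.fixture(scope="session")
def tiny_panel():
    """12-gene panel for fast cohort simulations."""
    return generate_panel(12, 2, seed=11)


@pytest.fixture()
def small_config():
    return CohortConfig(seed=11, n_genes=20, bins_per_gene=5)


def make_config(**kwargs):
    defaults = dict(seed=11, n_genes=12, bins_per_gene=2)
    defaults.update(kwargs)
    return CohortConfig(**defaults)
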