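import numpy as np
import pytest

from dmescreen import synthetic_data as sd


@pytest.fixture
def config():
    return sd.SimConfig(seed=11)


@pytest.fixture
def noiseless_config():
    return sd.SimConfig(seed=11, noise_cv=0.0)


@pytest.fixture
def planted_genotypes():
    """One planted violation per filter plus four clean sites."""
    cfg = sd.SimConfig(seed=7)
    table, truth = sd.gen_genotype_table(cfg, {k: 1 for k in range(1, 7)}, n_clean=4)
    return table, truth
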