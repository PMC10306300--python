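import numpy as np
import pandas as pd
import pytest

from ifnomics import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    # compact cohort: fast, yet enough samples for stable group statistics
    return CohortConfig(n_t21=60, n_control=30, n_genes=300, n_chr21_genes=30,
                        n_isg_true=10, n_isg_null=15, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    # the study-scale cohort the analyses assume (300 T21 / 100 control)
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
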