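import numpy as np
import pytest

from dynmod import SimulationConfig, generate_cohort, align_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort shared by read-only tests.

    56 nodes (8 per planted module, modules = the 7 canonical networks),
    400 time points, strong planted structure and a strong negative
    phenotype-stability link.
    """
    config = SimulationConfig(
        n_subjects=12, n_nodes=56, n_timepoints=400, n_modules=7,
        base_within_cov=0.6, base_between_cov=0.15,
        stability_range=(0.0, 0.15), phenotype_slope=-1.0,
        noise_sd=0.3, seed=1234,
    )
    series, phenotype, labeling, truth = generate_cohort(config)
    cohort = align_cohort(series, labeling, phenotype)
    return config, cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260919)
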