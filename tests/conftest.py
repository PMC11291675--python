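import numpy as np
import pytest

import hlapqtl as h


@pytest.fixture(scope="session")
def catalog():
    return h.demo_catalog()


@pytest.fixture(scope="session")
def cohort(catalog):
    """Shared mid-size cohort with the default causal architecture."""
    cfg = h.demo_config(n_individuals=2000, n_proteins=4, seed=11)
    return h.simulate_cohort(cfg, catalog)


@pytest.fixture(scope="session")
def prepared(cohort):
    return h.prepare_panel(cohort.phenotypes, cohort.covariates)


@pytest.fixture(scope="session")
def all_variants(cohort, catalog):
    return h.full_variant_matrix(cohort.observed_dosages, catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
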