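import warnings

import pytest

from ctclineage import SimulationConfig, simulate_cohort
from ctclineage import pipeline as pl

SEED = 11


@pytest.fixture(scope="session")
def cohort():
    """One study-scale cohort shared by the whole suite (fixed seed)."""
    return simulate_cohort(SimulationConfig(seed=SEED))


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    """Full pipeline run on the shared cohort (computed once)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pl.run_pipeline(cohort, ratchet_iterations=60, seed=SEED)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast unit-level checks."""
    cfg = SimulationConfig(seed=7, target_size_mb=26.0, n_chromosomes=3,
                           n_cnas=4, fpr_per_mb=5.0, n_pt_specimens=4,
                           n_ctc_pools=3, n_clones=9)
    return simulate_cohort(cfg)
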