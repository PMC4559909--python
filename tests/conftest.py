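import numpy as np
import pytest

from vegfsema import binding, cohort
from vegfsema.panel import default_vegf_sema_panel


@pytest.fixture(scope="session")
def panel():
    return default_vegf_sema_panel()


@pytest.fixture(scope="session")
def sim_cohort():
    """GSE35988-like synthetic cohort (12 benign / 49 primary / 27 metastatic)."""
    m, truth = cohort.simulate_cohort(cohort.CohortConfig.gse35988_like(), seed=11)
    return m, truth


@pytest.fixture(scope="session")
def bcr_cohort():
    """Large primary cohort with BCR outcomes attached."""
    cfg = cohort.CohortConfig.bcr_cohort()
    m, truth = cohort.simulate_cohort(cfg, seed=7)
    m = cohort.attach_bcr_outcomes(m, cfg, seed=8, truth=truth)
    return m, truth


@pytest.fixture(scope="session")
def multimet_cohort():
    """21 normals plus 18 metastases from 5 patients."""
    m, truth = cohort.simulate_cohort(cohort.CohortConfig.multi_metastasis(), seed=3)
    return m, truth


@pytest.fixture(scope="session")
def default_params():
    return binding.default_parameters()


@pytest.fixture(scope="session")
def nominal_steady_state(default_params):
    compiled = binding.CompiledNetwork(default_params)
    return binding.simulate_to_steady_state(compiled), compiled


@pytest.fixture(scope="session")
def binding_population(sim_cohort, default_params):
    """Per-sample steady states for the full 88-sample simulation cohort."""
    m, _ = sim_cohort
    return binding.run_population(default_params, m), m
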