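import numpy as np
import pytest

from semcohort import GeneratorConfig, fit
from semcohort.cohort import simulate_baseline
from semcohort.pipeline import preprocess, run_sem_stage, sel_age_quotient


@pytest.fixture()
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def baseline_50k():
    """One large baseline cohort shared across calibration tests."""
    return simulate_baseline(GeneratorConfig(seed=1), n=50_000)


@pytest.fixture(scope="session")
def paper_fit_50k(baseline_50k):
    """Structural-model fit to the 50k synthetic baseline."""
    table, _ = preprocess(baseline_50k)
    table, _ = sel_age_quotient(table)
    result = run_sem_stage(table, seed=1)
    assert result.converged
    return result


def standardized_path(fit_result, source, target):
    lat = list(fit_result.spec.latent_names)
    std = fit_result.standardized
    return float(std.beta[lat.index(target), lat.index(source)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
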