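import pytest
from hypothesis import HealthCheck, settings

from paircnv import CohortSpec, generate_cohort

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """The reference cohort: 9 patients, noise 0.2, seed 1."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(seed=7, n_genes=400, n_segments=2, genes_per_segment=20,
                      n_de_per_group=(60, 20, 5), n_prognostic=30)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)
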