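import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort: 8 stable and 6 labile genes, 2 species."""
    from cypstab.synthetic import CohortConfig, generate_cohort

    return generate_cohort(
        CohortConfig(seed=7, n_species=2, genes_per_class=(8, 6))
    )


@pytest.fixture(scope="session")
def small_bundle(small_cohort, tmp_path_factory):
    """The small cohort written to disk; returns the path map."""
    out = tmp_path_factory.mktemp("bundle")
    return small_cohort.write(out)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-size cohort (50 genes per class, 4 species)."""
    from cypstab.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(seed=1))
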