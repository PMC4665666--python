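import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rsalogit import (
    FixtureConfig,
    ModelSpec,
    build_design,
    complete_records,
    fit_logistic,
    simulate_dataset,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mixed_dataset():
    """A moderate synthetic study with both homology branches, oligomers and
    interfacial residues.  Shared read-only across tests."""
    return simulate_dataset(FixtureConfig(n_chains=24, seed=11))


@pytest.fixture(scope="session")
def branch_fits(mixed_dataset):
    """Classic model on the optimum branch, non-homology model on the rest."""
    records = mixed_dataset.records
    fits = {}
    spec_opt = ModelSpec.named("classic")
    optimum = [r for r in records if r.homology_status == "optimum"]
    fits["optimum"] = fit_logistic(
        build_design(complete_records(optimum, spec_opt), spec_opt)
    )
    spec_nh = ModelSpec.named("non_homology")
    non_opt = [r for r in records if r.homology_status == "non_optimum"]
    fits["non_optimum"] = fit_logistic(
        build_design(complete_records(non_opt, spec_nh), spec_nh)
    )
    return fits


@pytest.fixture
def rng():
    return np.random.default_rng(7)
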