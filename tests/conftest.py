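import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One small simulated cohort written to disk, shared across tests."""
    from splicestrat.simulate import SimConfig, simulate_cohort

    outdir = tmp_path_factory.mktemp("bundle")
    bundle = simulate_cohort(SimConfig(seed=7, n_tumor=60, n_normal=40))
    paths = bundle.write(outdir)
    return bundle, paths
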