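import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from vhhprof import toy_reference  # noqa: E402
from vhhprof.annotate import annotate_all  # noqa: E402
from vhhprof.simulate import SimulationConfig, simulate_repertoire  # noqa: E402


@pytest.fixture(scope="session")
def germline():
    v_genes, j_genes = toy_reference()
    return v_genes, j_genes


@pytest.fixture(scope="session")
def small_repertoire():
    """300 clones at default SHM, error-free reads; annotated once."""
    cfg = SimulationConfig(n_clones=300, seed=3)
    cfg.sequencing.error_rate = 0.0
    clones, truths = simulate_repertoire(cfg)
    v_genes, j_genes = toy_reference()
    records = annotate_all(clones, v_genes, j_genes)
    return cfg, clones, truths, records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
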