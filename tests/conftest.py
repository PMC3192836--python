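import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mirdiv.config import SimConfig
from mirdiv.synthetic import simulate_counts, simulate_read_stacks


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=42, n_mirna=40, n_genes=400, depth=1e5)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """Stacks, loci and truth for a small default-condition simulation."""
    return simulate_read_stacks(small_cfg)


@pytest.fixture(scope="session")
def de_sim():
    """Count-level simulation with implanted DE at study conditions."""
    cfg = SimConfig(seed=7, n_mirna=200, depth=1e6, de_fraction=0.1, de_fold=4.0)
    counts, meta, truth = simulate_counts(cfg)
    return cfg, counts, meta, truth
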