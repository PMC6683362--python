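import pytest

from hybridogen.diagnostics import find_diagnostic_loci
from hybridogen.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A clean five-class cohort: no noise, no missing data, depth 50."""
    cfg = SimConfig(
        n_per_class={"LL": 5, "RR": 5, "LR": 5, "LLR": 5, "LRR": 5},
        n_loci_total=200,
        n_diagnostic=80,
        depth_mean=50.0,
        depth_dispersion="poisson",
        seq_error=0.0,
        missing_rate=0.0,
        seed=11,
    )
    gm, pm, truth = simulate_cohort(cfg)
    return cfg, gm, pm, truth


@pytest.fixture(scope="session")
def small_panel(small_cohort):
    _, gm, pm, _ = small_cohort
    return find_diagnostic_loci(gm, pm)
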