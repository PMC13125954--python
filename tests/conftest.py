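import pytest

from hybridotype.simhyb import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def sim_cohort():
    """A mixed cohort at study-like composition, desk scale (200 markers)."""
    cfg = SimConfig(seed=42, n_markers=200, prop_diagnostic=0.3)
    table, labels, truth = simulate_cohort(cfg)
    return table, labels, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Error-free sequencing (epsilon=0) with fully fixed parental pools."""
    cfg = SimConfig(
        seed=7,
        n_markers=150,
        prop_diagnostic=0.3,
        n_l=5,
        n_r=5,
        n_e2=3,
        n_e3_llr=2,
        n_e3_lrr=1,
        epsilon=0.0,
        mean_depth=60.0,
    )
    table, labels, truth = simulate_cohort(cfg)
    return table, labels, truth
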