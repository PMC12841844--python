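import pytest
from hypothesis import HealthCheck, settings

import fourway

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """An 800-gene factorial dataset with all planted effect classes."""
    cfg = fourway.SimulationConfig(
        n_genes=800,
        baseline_log_mean=5.0,
        baseline_log_sd=1.0,
        frac_surgery_common=0.05,
        frac_diet_common=0.08,
        frac_reversal=0.03,
        frac_interaction=0.02,
        seed=123,
    )
    matrix, annotation, truth = fourway.generate_factorial_counts(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def small_contrasts(small_dataset):
    _, matrix, _ = small_dataset
    return fourway.run_standard_contrasts(matrix)
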