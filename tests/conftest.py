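import numpy as np
import pytest

from metagcn import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """70 subjects, 30 regions, imbalanced 10/20/40, strong planted signal."""
    return generate_cohort(
        CohortConfig(
            n_regions=30,
            class_counts=(10, 20, 40),
            n_signal_edges=60,
            effect_size=0.3,
            noise_sd=0.1,
            demo_assoc=0.8,
            seed=123,
        )
    )


@pytest.fixture(scope="session")
def null_small_cohort():
    """Same shape as small_cohort but with no class signal anywhere."""
    return generate_cohort(
        CohortConfig(
            n_regions=30,
            class_counts=(10, 20, 40),
            n_signal_edges=60,
            effect_size=0.0,
            noise_sd=0.1,
            demo_assoc=0.0,
            seed=321,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
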