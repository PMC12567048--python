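import numpy as np
import pandas as pd
import pytest

from cryptkin.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Low-noise 150-sample cohort with ~10% planted fusions."""
    return generate_cohort(
        CohortSpec(n_samples=150, cohort_label="T", fusion_fraction=0.10,
                   noise_sd=0.3, seed=11)
    )


@pytest.fixture(scope="session")
def two_cohorts():
    """Two cohorts with unequal gene panels, as the pooled analysis expects."""
    a = generate_cohort(
        CohortSpec(n_samples=400, cohort_label="A", fusion_fraction=0.085,
                   noise_sd=0.3, seed=3, n_background_genes=300)
    )
    b = generate_cohort(
        CohortSpec(n_samples=400, cohort_label="B", fusion_fraction=0.085,
                   noise_sd=0.3, seed=4, n_background_genes=200)
    )
    return {"A": a, "B": b}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
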