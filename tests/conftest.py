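import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ajstrat import CohortConfig, ExpressionMatrix, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_expression(values, protein_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    p, n = values.shape
    protein_ids = protein_ids or [f"P{i:03d}" for i in range(p)]
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(n)]
    return ExpressionMatrix(pd.DataFrame(values, index=protein_ids, columns=sample_ids))


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A faster cohort for I/O and pipeline plumbing tests."""
    config = CohortConfig(
        n_samples=60, n_proteins=300, n_decoy_modules=2,
        histology_signature_size=40, n_random_sets=10, seed=3,
    )
    return config, generate_cohort(config)
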