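import numpy as np
import pandas as pd
import pytest

from tpsad import (
    CohortSimParams,
    ExpressionSimParams,
    simulate_cohort,
    simulate_expression_studies,
)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A 400-patient synthetic cohort, shared across tests (read-only)."""
    return simulate_cohort(CohortSimParams(n_patients=400), seed=11)


@pytest.fixture(scope="session")
def planted_studies():
    """Five studies with the 25-gene cassette planted down and AR up."""
    return simulate_expression_studies(
        ExpressionSimParams(n_studies=5, n_genes=300, samples_per_class=20), seed=5
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
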