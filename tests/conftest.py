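import numpy as np
import pandas as pd
import pytest

from stagenorm.io_formats import GenomicMatrix, SampleMetadata
from stagenorm.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture
def tiny_matrix() -> GenomicMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [0.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return GenomicMatrix(values=values, unit="log2_plus1")


@pytest.fixture
def two_site_counts():
    """2 sites x (2 early + 2 advanced), small integer counts."""
    samples = ["a_E1", "a_E2", "a_A1", "a_A2", "b_E1", "b_E2", "b_A1", "b_A2"]
    rng = np.random.default_rng(11)
    values = pd.DataFrame(
        rng.integers(1, 50, size=(3, 8)).astype(float),
        index=["g1", "g2", "g3"],
        columns=samples,
    )
    matrix = GenomicMatrix(values=values, unit="raw_count")
    metadata = [
        SampleMetadata(
            sample_id=s,
            primary_site="siteA" if s.startswith("a") else "siteB",
            stage="early" if "_E" in s else "advanced",
        )
        for s in samples
    ]
    return matrix, metadata


@pytest.fixture(scope="session")
def default_cohort():
    """One default-regime simulated cohort shared by read-only tests."""
    config = SimulationConfig(seed=123)
    return simulate_cohort(config)
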