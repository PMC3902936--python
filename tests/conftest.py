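import numpy as np
import pandas as pd
import pytest

from remsig import DoseResponseMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def small_dose():
    """3 drugs × 4 cells with one missing GI50."""
    df = pd.DataFrame(
        [[-6.0, -5.5, -7.0, -6.2], [-8.0, np.nan, -7.5, -7.8], [-5.0, -5.1, -4.9, -5.0]],
        index=["D1", "D2", "D3"],
        columns=["c1", "c2", "c3", "c4"],
    )
    return DoseResponseMatrix(df)


@pytest.fixture
def null_expression(rng):
    """50 genes × 12 samples of pure Gaussian noise, labelled 6v6."""
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"s{i:02d}" for i in range(12)]
    labels = {s: ("A" if i < 6 else "B") for i, s in enumerate(samples)}
    values = pd.DataFrame(rng.normal(0, 1, (50, 12)), index=genes, columns=samples)
    return ExpressionMatrix(values, sample_labels=labels)
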