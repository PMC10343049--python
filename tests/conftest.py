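import numpy as np
import pandas as pd
import pytest

from degpattern import CountMatrix, NormFactors


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Six samples in a 1x2 layout with NB-ish counts, 40 genes."""
    rng = np.random.default_rng(42)
    counts = rng.negative_binomial(10, 0.1, size=(40, 6))
    df = pd.DataFrame(
        counts,
        index=[f"g{i}" for i in range(40)],
        columns=[f"s{j}" for j in range(6)],
    )
    meta = pd.DataFrame(
        {
            "sample_id": df.columns,
            "factor_a": ["X"] * 6,
            "factor_b": ["P", "P", "P", "L", "L", "L"],
        }
    )
    return CountMatrix(df, meta)


@pytest.fixture
def unit_factors():
    """NormFactors with unit factors and equal library sizes for 2 samples."""

    def make(n_samples: int = 2, lib_size: float = 1e6) -> NormFactors:
        return NormFactors(
            np.ones(n_samples),
            np.full(n_samples, lib_size),
            np.array([f"s{j}" for j in range(n_samples)]),
        )

    return make
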