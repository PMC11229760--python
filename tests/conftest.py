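import numpy as np
import pandas as pd
import pytest

from microsig.abundance_io import AbundanceTable


@pytest.fixture
def tiny_table() -> AbundanceTable:
    """2 samples x 2 taxa, rows summing to 100."""
    values = pd.DataFrame(
        [[60.0, 40.0], [30.0, 70.0]],
        index=["A", "B"], columns=["tax1", "tax2"],
    )
    group = pd.Series([0, 1], index=["A", "B"])
    return AbundanceTable(values=values, group=group, rank="genus")


@pytest.fixture
def small_table() -> AbundanceTable:
    """12 samples x 5 taxa with zeros and a rare taxon."""
    rng = np.random.default_rng(7)
    raw = rng.gamma(2.0, 1.0, size=(12, 5)) * np.array([50, 30, 10, 5, 0.2])
    raw[raw < 0.4] = 0.0
    pct = 100 * raw / raw.sum(axis=1, keepdims=True)
    idx = [f"S{i}" for i in range(12)]
    values = pd.DataFrame(pct, index=idx, columns=[f"t{j}" for j in range(5)])
    group = pd.Series([0] * 6 + [1] * 6, index=idx)
    return AbundanceTable(values=values, group=group, rank="genus")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
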