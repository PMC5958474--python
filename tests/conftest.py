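import numpy as np
import pandas as pd
import pytest

from genorisk import load_panel, normalize_est


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def figure2_panel():
    return load_panel(variant="figure2")


@pytest.fixture()
def small_table():
    """3 genes x 3 tissues with hand-checkable TPM values."""
    counts = pd.DataFrame(
        {
            "heart": [2, 0, 30],
            "liver": [100, 5, 0],
            "lung": [0, 0, 1],
        },
        index=["G1", "G2", "G3"],
    )
    totals = pd.Series(
        {"heart": 200_000, "liver": 1_000_000, "lung": 100_000}, dtype=float
    )
    return normalize_est(counts, totals)
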