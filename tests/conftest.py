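import numpy as np
import pandas as pd
import pytest

from qsardnn.dataset_io import ActivityTable
from qsardnn.synthetic import toy_molecules


@pytest.fixture(scope="session")
def toys():
    return toy_molecules()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_table(rng: np.random.Generator, n: int, columns: list[str]) -> ActivityTable:
    """Small random activity table for I/O and alignment tests."""
    counts = rng.integers(0, 5, size=(n, len(columns)))
    return ActivityTable(
        molecule_ids=[f"M{i:03d}" for i in range(n)],
        activities=rng.normal(5.0, 1.0, size=n),
        descriptors=pd.DataFrame(counts, columns=columns),
    )
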