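import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from scnpheno import CtMatrix, default_config, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One draw of the frozen default synthetic configuration."""
    return generate_dataset(default_config())


@pytest.fixture(scope="session")
def default_ddct(default_dataset):
    from scnpheno import median_center, qc_filter, to_minus_dct

    ct, truth = default_dataset
    ct_f, _ = qc_filter(ct)
    return median_center(to_minus_dct(ct_f)), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_ct(values, nondetect=None, housekeeping=(), treatment=None):
    """Small CtMatrix builder for hand-constructed fixtures."""
    values = pd.DataFrame(values)
    values.index = [f"g{i}" for i in range(values.shape[0])] if values.index.dtype != object else values.index
    if nondetect is None:
        nondetect = pd.DataFrame(False, index=values.index, columns=values.columns)
    else:
        nondetect = pd.DataFrame(nondetect, index=values.index, columns=values.columns)
    if treatment is None:
        treatment = pd.Series("LP", index=values.columns)
    return CtMatrix(
        values=values,
        nondetect=nondetect,
        treatment=treatment,
        housekeeping=list(housekeeping),
    )
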