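import numpy as np
import pytest

from missgen.structure import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def planted_mask(n=200, block_sizes=(4, 3, 3), sm_rates=(0.0, 0.4, 0.25), seed=0):
    """Mask with planted sub-study blocks: per block, a random subset of
    subjects loses the whole block (structured); no unstructured noise."""
    rng = np.random.default_rng(seed)
    d = sum(block_sizes)
    mask = np.zeros((n, d), dtype=np.int8)
    labels = np.concatenate(
        [np.full(s, i) for i, s in enumerate(block_sizes)]
    )
    for i, rate in enumerate(sm_rates):
        rows = rng.random(n) < rate
        mask[np.ix_(rows, np.flatnonzero(labels == i))] = 1
    return mask, labels


@pytest.fixture
def small_data(rng):
    """Tiny mixed-type DataMatrix with a few missing cells."""
    values = rng.standard_normal((12, 4))
    values[:, 3] = (values[:, 3] > 0).astype(float)
    values[0, 1] = np.nan
    values[3, 3] = np.nan
    return DataMatrix(
        values=values,
        var_types=np.array(["continuous"] * 3 + ["binary"], dtype=object),
        var_ids=np.array([f"v{j}" for j in range(4)], dtype=object),
        subject_ids=np.array([f"s{i}" for i in range(12)], dtype=object),
    )
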