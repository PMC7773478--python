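import numpy as np
import pytest

from s5m.data import LabeledSeries, SeriesDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(values_list, labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(values_list))]
    return SeriesDataset(series=tuple(
        LabeledSeries(values=np.asarray(v, dtype=float), label=int(l), id=i)
        for v, l, i in zip(values_list, labels, ids)
    ))


@pytest.fixture
def toy_dataset():
    """Four series, two cases carrying the pattern (1, 2, 3), two noise controls."""
    return make_dataset(
        [[0, 1, 2, 3, 0], [1, 2, 3, 1, 1], [5, 0, 5, 0, 5], [0, 6, 0, 6, 0]],
        [1, 1, 0, 0],
    )
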