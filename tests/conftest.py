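import numpy as np
import pytest

from rbconn.volumes import MaskedSeries, VolumeGrid, standardize


def make_series(n: int, p: int, seed: int = 0, tr: float = 2.0,
                standardized: bool = True, data: np.ndarray | None = None) -> MaskedSeries:
    """Random (or given) N x p series on a p x 1 x 1 grid."""
    rng = np.random.default_rng(seed)
    if data is None:
        data = rng.standard_normal((n, p))
    coords = np.column_stack([np.arange(p), np.zeros(p, int), np.zeros(p, int)])
    series = MaskedSeries(data=np.asarray(data, float), voxel_index=coords,
                          tr=tr, grid=VolumeGrid((p, 1, 1)))
    return standardize(series) if standardized else series


@pytest.fixture
def rng():
    return np.random.default_rng(20240217)
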