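import numpy as np
import pytest

from connectograd.io import BoldData, VolumeGrid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_bold_pair(rng):
    """Generic small (ROI, target) pair of random BOLD data, T=50."""
    roi_grid = VolumeGrid((5, 2, 2), np.diag([2.0, 2.0, 2.0, 1.0]))
    tgt_grid = VolumeGrid((6, 5, 1), np.diag([2.0, 2.0, 2.0, 1.0]))
    roi = BoldData(roi_grid, np.ones((5, 2, 2), bool),
                   rng.standard_normal((50, 20)))
    tgt = BoldData(tgt_grid, np.ones((6, 5, 1), bool),
                   rng.standard_normal((50, 30)))
    return roi, tgt


def raw_fingerprints(roi: BoldData, target: BoldData) -> np.ndarray:
    """Brute-force fingerprints: ROI-voxel x target-voxel Pearson correlations."""
    def z(a):
        sd = a.std(axis=0)
        return (a - a.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    return (z(roi.series).T @ z(target.series)) / roi.n_timepoints
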