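import warnings

import numpy as np
import pytest

from periradiomics.grid import BinaryMask, Volume

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return Volume(np.asarray(values, dtype=float), np.asarray(spacing))


def make_mask(values, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(values, dtype=bool), np.asarray(spacing))


def random_roi(rng, shape=(5, 5, 5), ng=4, density=0.7):
    """Random discretized ROI: (levels grid, roi mask, ng)."""
    roi = rng.random(shape) < density
    if not roi.any():
        roi.flat[0] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[roi] = rng.integers(1, ng + 1, size=int(roi.sum()))
    return levels, roi, int(max(1, levels.max()))
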