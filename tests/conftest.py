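from __future__ import annotations

import numpy as np
import pytest

from radrobust.features.discretize import DiscretizedRegion


def random_region(rng: np.random.Generator, max_size: int = 32, max_ng: int = 6) -> DiscretizedRegion:
    """A random discretized region (levels 1..ng, patchy mask) for oracle tests."""
    h = int(rng.integers(2, max_size + 1))
    w = int(rng.integers(2, max_size + 1))
    ng = int(rng.integers(1, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=(h, w))
    mask = rng.random((h, w)) < rng.uniform(0.4, 0.95)
    if not mask.any():
        mask[h // 2, w // 2] = True
    levels = np.where(mask, levels, 0)
    return DiscretizedRegion(levels=levels, mask=mask, ng=ng, bin_edges=np.array([]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
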