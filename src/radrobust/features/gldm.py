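"""Grey-level dependence matrix (GLDM) features.

For every in-mask pixel, the dependence is the number of in-mask
neighbours within Chebyshev distance ``delta`` whose level differs by at
most ``alpha``.  The matrix counts pixels by (level, dependence).

The dependence of an isolated pixel is 0; emphasis formulas therefore
use the dependence *size* (dependence + 1, i.e. including the centre
pixel) as the column index so the small-dependence emphasis stays
finite.
"""
from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRegion


def _chebyshev_offsets(delta: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-delta, delta + 1)
        for dc in range(-delta, delta + 1)
        if (dr, dc) != (0, 0)
    ]


def dependence_matrix(
    region: DiscretizedRegion, delta: int = 1, alpha: int = 0
) -> np.ndarray:
    """Counts P[level-1, dependence]; columns 0..max Chebyshev neighbours."""
    if delta < 1:
        raise ValueError("delta must be ≥ 1")
    if alpha < 0:
        raise ValueError("alpha must be ≥ 0")
    lv, mk = region.levels, region.mask
    h, w = lv.shape
    dep = np.zeros(lv.shape, dtype=np.int64)
    for dr, dc in _chebyshev_offsets(delta):
        src = (slice(max(0, -dr), h - max(0, dr)), slice(max(0, -dc), w - max(0, dc)))
        dst = (slice(max(0, dr), h + min(0, dr)), slice(max(0, dc), w + min(0, dc)))
        ok = mk[src] & mk[dst] & (np.abs(lv[src] - lv[dst]) <= alpha)
        dep[src] += ok
    n_cols = (2 * delta + 1) ** 2  # dependence ranges 0..(2δ+1)²−1
    counts = np.zeros((region.ng, n_cols))
    np.add.at(counts, (lv[mk] - 1, dep[mk]), 1.0)
    return counts


def gldm_features(
    region: DiscretizedRegion, delta: int = 1, alpha: int = 0
) -> dict[str, float]:
    p = dependence_matrix(region, delta, alpha)
    nz = p.sum()
    size = np.arange(1, p.shape[1] + 1)[None, :]  # dependence + 1
    row_sums = p.sum(axis=1)
    col_sums = p.sum(axis=0)
    probs = p[p > 0] / nz
    return {
        "GLDM.sde": float((p / size**2).sum() / nz),
        "GLDM.lde": float((p * size**2).sum() / nz),
        "GLDM.gln": float((row_sums**2).sum() / nz),
        "GLDM.dn": float((col_sums**2).sum() / nz),
        "GLDM.dep_entropy": float(-(probs * np.log2(probs)).sum()),
    }
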