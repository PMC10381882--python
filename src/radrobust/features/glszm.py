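"""Grey-level size zone matrix (GLSZM) features.

A zone is an 8-connected component of equal-level in-mask pixels; the
matrix counts zones by (level, size).
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedRegion

_EIGHT = np.ones((3, 3), dtype=bool)


def size_zone_table(region: DiscretizedRegion) -> list[tuple[int, int]]:
    """All (level, zone_size) pairs, one per connected zone."""
    zones: list[tuple[int, int]] = []
    for level in range(1, region.ng + 1):
        labelled, n = ndimage.label(region.levels == level, structure=_EIGHT)
        if n:
            sizes = np.bincount(labelled.ravel())[1:]
            zones.extend((level, int(s)) for s in sizes)
    return zones


def glszm_features(region: DiscretizedRegion) -> dict[str, float]:
    zones = size_zone_table(region)
    nz = len(zones)
    levels = np.array([z[0] for z in zones], dtype=float)
    sizes = np.array([z[1] for z in zones], dtype=float)
    level_counts = np.bincount(levels.astype(int))
    size_counts = np.bincount(sizes.astype(int))
    return {
        "GLSZM.sae": float((1.0 / sizes**2).sum() / nz),
        "GLSZM.lae": float((sizes**2).sum() / nz),
        "GLSZM.zp": float(nz / region.n_pixels),
        "GLSZM.gln": float((level_counts.astype(float) ** 2).sum() / nz),
        "GLSZM.szn": float((size_counts.astype(float) ** 2).sum() / nz),
    }
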