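"""Grey-level discretization of a masked region.

Equal-width bins with a fixed bin *count* spanning the in-mask min–max,
recomputed per mask, so levels are scale-free across 8- and 16-bit
inputs.  Levels run 1..Ng; 0 is the background sentinel.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import types
from ..types import GreyImage


@dataclass(frozen=True)
class DiscretizedRegion:
    """Grey levels (1..Ng in-mask, 0 outside) over the mask bounding box."""

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    bin_edges: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def discretize(image: GreyImage | np.ndarray, mask: np.ndarray, n_bins: int = 64) -> DiscretizedRegion:
    """Bin in-mask intensities into ``n_bins`` equal-width levels.

    A constant region collapses to a single level (Ng = 1) regardless of
    ``n_bins``.  The grids are cropped to the mask bounding box; features
    depend only on in-mask pixels, so this is purely an optimization.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be ≥ 1")
    px = image.pixels if isinstance(image, GreyImage) else np.asarray(image)
    m = types.validate_mask(mask, px.shape)

    rows, cols = np.nonzero(m)
    sl = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
    px, m = px[sl], m[sl]

    vals = px[m].astype(float)
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(px.shape, dtype=np.int64)
    if lo == hi:
        levels[m] = 1
        return DiscretizedRegion(levels=levels, mask=m, ng=1, bin_edges=np.array([lo, hi]))
    width = (hi - lo) / n_bins
    lev = np.floor((px[m].astype(float) - lo) / width).astype(np.int64) + 1
    levels[m] = np.clip(lev, 1, n_bins)
    edges = np.linspace(lo, hi, n_bins + 1)
    return DiscretizedRegion(levels=levels, mask=m, ng=n_bins, bin_edges=edges)
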