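"""First-order intensity statistics of the in-mask pixels.

All moments use the population denominator N; skewness is m3/m2^1.5 and
kurtosis is the non-excess m4/m2².  When m2 = 0 (constant region) both
are defined as 0 so constant phantoms stay in the table.  Entropy is
computed on the discretized histogram in bits.
"""
from __future__ import annotations

import numpy as np

from .. import types
from ..types import GreyImage
from .discretize import discretize


def first_order(
    image: GreyImage | np.ndarray, mask: np.ndarray, n_bins: int = 64
) -> dict[str, float]:
    px = image.pixels if isinstance(image, GreyImage) else np.asarray(image)
    m = types.validate_mask(mask, px.shape)
    x = px[m].astype(float)
    n = x.size
    mean = x.mean()
    centred = x - mean
    m2 = float((centred**2).mean())
    if m2 > 0:
        skewness = float((centred**3).mean()) / m2**1.5
        kurtosis = float((centred**4).mean()) / m2**2
    else:
        skewness = 0.0
        kurtosis = 0.0

    region = discretize(px, m, n_bins)
    counts = np.bincount(region.levels[region.mask], minlength=region.ng + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())

    return {
        "FO.mean": float(mean),
        "FO.variance": m2,
        "FO.skewness": skewness,
        "FO.kurtosis": kurtosis,
        "FO.entropy": entropy,
        "FO.energy": float((x**2).sum()),
        "FO.rms": float(np.sqrt((x**2).mean())),
        "FO.maximum": float(x.max()),
        "FO.minimum": float(x.min()),
        "FO.range": float(x.max() - x.min()),
        "FO.mad": float(np.abs(centred).mean()),
        "FO.median": float(np.median(x)),
        "FO.p10": float(np.percentile(x, 10)),
        "FO.p90": float(np.percentile(x, 90)),
    }
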