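"""Grey-level co-occurrence matrix (GLCM) features.

Co-occurrences are counted between in-mask pixel pairs at a given
distance along each angle, symmetrized by adding the transpose, and
normalized to sum 1.  Features are computed per angle and averaged over
the angles that produced at least one pair.
"""
from __future__ import annotations

import numpy as np

from .discretize import DiscretizedRegion

#: angle (degrees) → (row, col) step for distance 1
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

DEFAULT_ANGLES = (0, 45, 90, 135)


def cooccurrence_matrix(
    region: DiscretizedRegion, distance: int, angle: int
) -> np.ndarray:
    """Symmetrized (unnormalized) co-occurrence counts for one angle."""
    if distance < 1:
        raise ValueError("distance must be ≥ 1")
    dr, dc = (d * distance for d in ANGLE_OFFSETS[angle])
    lv, mk = region.levels, region.mask
    h, w = lv.shape
    src = (slice(max(0, -dr), h - max(0, dr)), slice(max(0, -dc), w - max(0, dc)))
    dst = (slice(max(0, dr), h + min(0, dr)), slice(max(0, dc), w + min(0, dc)))
    valid = mk[src] & mk[dst]
    i = lv[src][valid] - 1
    j = lv[dst][valid] - 1
    counts = np.zeros((region.ng, region.ng))
    np.add.at(counts, (i, j), 1.0)
    return counts + counts.T


def _glcm_features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    diff = i - j
    nz = p > 0
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    sd_i = float(np.sqrt((((i - mu_i) ** 2) * p).sum()))
    sd_j = float(np.sqrt((((j - mu_j) ** 2) * p).sum()))
    if sd_i > 0 and sd_j > 0:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j))
    else:
        correlation = 1.0  # constant region: perfectly correlated by convention
    return {
        "GLCM.joint_energy": float((p**2).sum()),
        "GLCM.joint_entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
        "GLCM.contrast": float((p * diff**2).sum()),
        "GLCM.correlation": correlation,
        "GLCM.idm": float((p / (1.0 + diff**2)).sum()),
        "GLCM.dissimilarity": float((p * np.abs(diff)).sum()),
    }


def glcm_features(
    region: DiscretizedRegion,
    distance: int = 1,
    angles: tuple[int, ...] = DEFAULT_ANGLES,
) -> dict[str, float]:
    per_angle: list[dict[str, float]] = []
    for angle in angles:
        counts = cooccurrence_matrix(region, distance, angle)
        total = counts.sum()
        if total == 0:
            continue
        per_angle.append(_glcm_features_one(counts / total))
    if not per_angle:
        # no valid pixel pair at any angle: features flagged missing
        return {k: float("nan") for k in _glcm_features_one(np.ones((1, 1)))}
    return {
        name: float(np.mean([f[name] for f in per_angle])) for name in per_angle[0]
    }
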