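"""Artificial over-/under-segmentation by scaled octagonal morphology.

The perturbation scale is 6% (configurable ``k``) of the mask's
equivalent-ellipse major axis, rounded to the nearest multiple of 3 px
(ties up) and clamped to a minimum of 3 px, so that a perceptible
perturbation always occurs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import SegmentationTriplet, validate_mask

logger = logging.getLogger(__name__)

DEFAULT_K = 0.06


def major_axis_length(mask: np.ndarray) -> float:
    """Major-axis length (px) of the ellipse with the same normalized
    second central moments as the foreground region.

    Equal to ``4·sqrt(λ1)`` where λ1 is the larger eigenvalue of the
    foreground pixel-coordinate covariance matrix with 1/12 added to each
    diagonal entry (pixel-extent correction), matching the convention of
    region-property tools that treat pixels as unit squares.
    """
    m = validate_mask(mask)
    coords = np.argwhere(m).astype(float)
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / len(coords)
    cov[0, 0] += 1.0 / 12.0
    cov[1, 1] += 1.0 / 12.0
    lam = np.linalg.eigvalsh(cov)[-1]
    return float(4.0 * np.sqrt(lam))


def perturbation_scale(mask: np.ndarray, k: float = DEFAULT_K) -> int:
    """Structuring-element scale d: nearest multiple of 3 to k × major axis.

    Ties round up; the result is clamped to ≥ 3 px.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    raw = k * major_axis_length(mask)
    d = int(np.floor(raw / 3.0 + 0.5)) * 3
    return max(d, 3)


@dataclass(frozen=True)
class StructuringElement:
    """Octagonal structuring element of origin-to-side distance ``d``.

    Membership: ``max(|dx|,|dy|) ≤ d`` and ``|dx|+|dy| ≤ round(d·√2)`` —
    the intersection of an L∞ ball and an L1 ball, realizing an octagon
    whose eight sides all lie at distance d (up to rounding) from the
    origin.
    """

    d: int
    footprint: np.ndarray

    @property
    def offsets(self) -> set[tuple[int, int]]:
        return {
            (int(r) - self.d, int(c) - self.d)
            for r, c in np.argwhere(self.footprint)
        }


def octagon_element(d: int) -> StructuringElement:
    if d < 1:
        raise ValueError("octagon scale d must be ≥ 1")
    r = np.arange(-d, d + 1)
    dy, dx = np.meshgrid(r, r, indexing="ij")
    l1_radius = int(round(d * np.sqrt(2.0)))
    footprint = (np.maximum(np.abs(dx), np.abs(dy)) <= d) & (
        np.abs(dx) + np.abs(dy) <= l1_radius
    )
    return StructuringElement(d=d, footprint=footprint)


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Minkowski sum of the mask and the element, clipped to the grid."""
    m = validate_mask(mask)
    return ndimage.binary_dilation(m, structure=se.footprint)


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Pixels whose se-neighbourhood lies entirely inside the mask.

    Out-of-grid positions count as background, so foreground touching the
    border erodes away (border contract; masks from the phantom generator
    keep a margin that makes this irrelevant).
    """
    m = validate_mask(mask)
    return ndimage.binary_erosion(m, structure=se.footprint, border_value=0)


def make_triplet(mask: np.ndarray, k: float = DEFAULT_K) -> SegmentationTriplet:
    """Build the original/over/under segmentation triplet for one ROI."""
    m = validate_mask(mask)
    d = perturbation_scale(m, k)
    se = octagon_element(d)
    over = dilate(m, se)
    under = erode(m, se)
    degenerate = not under.any()
    if degenerate:
        logger.warning(
            "erosion at scale d=%d emptied the mask (area %d px); "
            "triplet flagged degenerate",
            d,
            int(m.sum()),
        )
    return SegmentationTriplet(
        original=m,
        overestimated=over,
        underestimated=under,
        scale_d=d,
        degenerate=degenerate,
    )
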