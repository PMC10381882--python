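"""Radiomics feature extraction: first-order plus five texture families.

Features are computed on the (preprocessed) grey image restricted to a
binary mask, after per-mask min–max discretization.  The registry maps
each family to its extractor; feature ids are ``FAMILY.name``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..types import GreyImage, LesionRecord, SegmentationTriplet
from .discretize import DiscretizedRegion, discretize
from .firstorder import first_order
from .glcm import glcm_features
from .gldm import gldm_features
from .glrlm import glrlm_features
from .glszm import glszm_features
from .ngtdm import ngtdm_features

__all__ = [
    "DiscretizedRegion",
    "ExtractionConfig",
    "discretize",
    "extract_all",
    "extract_one",
    "feature_ids",
    "first_order",
    "glcm_features",
    "gldm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionConfig:
    n_bins: int = 64
    glcm_distance: int = 1
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    gldm_delta: int = 1
    gldm_alpha: int = 0
    ngtdm_delta: int = 1


def extract_one(
    image: GreyImage | np.ndarray,
    mask: np.ndarray,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> dict[str, float]:
    """Full feature vector for one (image, mask) pair."""
    values = first_order(image, mask, cfg.n_bins)
    region = discretize(image, mask, cfg.n_bins)
    values.update(glcm_features(region, cfg.glcm_distance, cfg.glcm_angles))
    values.update(gldm_features(region, cfg.gldm_delta, cfg.gldm_alpha))
    values.update(glrlm_features(region))
    values.update(glszm_features(region))
    values.update(ngtdm_features(region, cfg.ngtdm_delta))
    return values


def feature_ids(cfg: ExtractionConfig = ExtractionConfig()) -> list[str]:
    """All feature ids, sorted by (family, name) — the table column order."""
    probe = extract_one(np.arange(16, dtype=np.int64).reshape(4, 4), np.ones((4, 4), bool), cfg)
    return sorted(probe)


def extract_all(
    image: GreyImage | np.ndarray,
    triplet: SegmentationTriplet,
    record: LesionRecord,
    cfg: ExtractionConfig = ExtractionConfig(),
) -> list[dict[str, float | str]]:
    """Feature rows for every segmentation class of one lesion.

    Returns 3 rows (2 when the under-mask is degenerate, with a logged
    warning); discretization is recomputed per mask from that mask's own
    intensity range.
    """
    if triplet.degenerate:
        logger.warning(
            "case %s: degenerate under-segmentation; extracting original/over only",
            record.case_id,
        )
    rows: list[dict[str, float | str]] = []
    for seg_class, mask in triplet.masks().items():
        row: dict[str, float | str] = {
            "case_id": record.case_id,
            "abnormality": record.abnormality,
            "pathology": record.pathology,
            "view": record.view,
            "segmentation_class": seg_class,
        }
        row.update(extract_one(image, mask, cfg))
        rows.append(row)
    return rows
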