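"""Shared domain types: grey images, masks, lesion metadata, segmentation triplets."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

ABNORMALITIES = ("calcification", "mass")
PATHOLOGIES = ("benign", "malignant")
VIEWS = ("CC", "MLO")
SEGMENTATION_CLASSES = ("original", "over", "under")

#: metadata columns, in canonical order, of every long-format feature table
METADATA_COLUMNS = ("case_id", "abnormality", "pathology", "view", "segmentation_class")

FAMILIES = ("FO", "GLCM", "GLDM", "GLRLM", "GLSZM", "NGTDM")


@dataclass(frozen=True)
class GreyImage:
    """A 2D integer intensity grid with an explicit bit depth (8 or 16)."""

    pixels: np.ndarray
    bitdepth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("GreyImage requires a non-empty 2D grid")
        if self.bitdepth not in (8, 16):
            raise ValueError(f"bitdepth must be 8 or 16, got {self.bitdepth}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("GreyImage pixels must be integers")
        if px.min() < 0 or px.max() > self.max_value:
            raise ValueError("pixel values out of range for bitdepth")
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        return (1 << self.bitdepth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def validate_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Coerce to a boolean mask and enforce the BinaryMask invariants."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    m = m.astype(bool)
    if shape is not None and m.shape != tuple(shape):
        raise ValueError(f"mask shape {m.shape} does not match expected {tuple(shape)}")
    if not m.any():
        raise ValueError("mask has no foreground pixels")
    return m


@dataclass(frozen=True)
class LesionRecord:
    """Per-lesion metadata: identifier plus the three stratification labels."""

    case_id: str
    abnormality: str
    pathology: str
    view: str

    def __post_init__(self) -> None:
        if self.abnormality not in ABNORMALITIES:
            raise ValueError(f"unknown abnormality {self.abnormality!r}")
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology {self.pathology!r}")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")


@dataclass(frozen=True)
class SegmentationTriplet:
    """Original mask plus its morphological over-/under-estimates.

    Invariant: ``underestimated ⊆ original ⊆ overestimated``;
    ``degenerate`` is set iff the eroded mask is empty.
    """

    original: np.ndarray
    overestimated: np.ndarray
    underestimated: np.ndarray
    scale_d: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        orig = validate_mask(self.original)
        over = validate_mask(self.overestimated, orig.shape)
        under = np.asarray(self.underestimated).astype(bool)
        if under.shape != orig.shape:
            raise ValueError("underestimated mask shape mismatch")
        if (under & ~orig).any() or (orig & ~over).any():
            raise ValueError("containment violated: need under ⊆ original ⊆ over")
        if self.degenerate != (not under.any()):
            raise ValueError("degenerate flag inconsistent with eroded mask")
        object.__setattr__(self, "original", orig)
        object.__setattr__(self, "overestimated", over)
        object.__setattr__(self, "underestimated", under)

    def masks(self) -> dict[str, np.ndarray]:
        """Segmentation-class → mask mapping, omitting an empty under-mask."""
        out = {"original": self.original, "over": self.overestimated}
        if not self.degenerate:
            out["under"] = self.underestimated
        return out


@dataclass(frozen=True)
class PhantomCase:
    """A synthetic lesion image with its ground-truth mask and metadata."""

    image: GreyImage
    mask: np.ndarray
    record: LesionRecord
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", validate_mask(self.mask, self.image.shape))
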