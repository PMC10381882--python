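"""Readers and writers: grey images (PNG/TIFF/DICOM), masks, feature tables."""
from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .types import METADATA_COLUMNS, SEGMENTATION_CLASSES, GreyImage, validate_mask


def _bitdepth_for(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype in (np.uint16, np.int32, np.int64, np.uint32):
        return 8 if arr.max() <= 255 and arr.dtype == np.uint8 else 16
    raise ValueError(f"unsupported pixel dtype {arr.dtype}")


def read_image(path: str | Path) -> GreyImage:
    """Read a single-channel PNG/TIFF (or DICOM when pydicom is available)."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return _read_dicom(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: single-channel image required, got shape {arr.shape}")
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D image, got shape {arr.shape}")
    bitdepth = _bitdepth_for(arr)
    return GreyImage(pixels=arr.astype(np.uint8 if bitdepth == 8 else np.uint16), bitdepth=bitdepth)


def _read_dicom(path: Path) -> GreyImage:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError(
            "DICOM input requires the optional 'pydicom' package; "
            "convert to PNG/TIFF or install pydicom"
        ) from exc
    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = np.rint(arr * slope + intercept)
    arr = np.clip(arr, 0, None).astype(np.uint16)
    return GreyImage(pixels=arr, bitdepth=16)


def write_image(image: GreyImage, path: str | Path) -> None:
    """8-bit images as PNG, 16-bit as TIFF (lossless either way)."""
    path = Path(path)
    arr = image.pixels.astype(np.uint8 if image.bitdepth == 8 else np.uint16)
    iio.imwrite(path, arr)


def read_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a single-channel mask; any value > 0 is foreground."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: single-channel mask required")
    return validate_mask(arr > 0, expected_shape)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def order_feature_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Metadata columns first, then features sorted by (family, name)."""
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing metadata column(s): {', '.join(missing)}")
    feats = sorted(c for c in table.columns if c not in METADATA_COLUMNS)
    return table[list(METADATA_COLUMNS) + feats]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    # 17 significant digits guarantee a bit-exact float round trip
    order_feature_columns(table).to_csv(path, index=False, float_format=lambda v: format(v, ".17g"))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    table = order_feature_columns(table)
    bad = set(table["segmentation_class"].unique()) - set(SEGMENTATION_CLASSES)
    if bad:
        raise ValueError(f"unknown segmentation_class value(s): {sorted(bad)}")
    return table


def write_cohort(cases, outdir: str | Path) -> Path:
    """Write phantom images, masks and a metadata CSV for a cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for case in cases:
        stem = case.record.case_id
        ext = "png" if case.image.bitdepth == 8 else "tif"
        write_image(case.image, outdir / f"{stem}.{ext}")
        write_mask(case.mask, outdir / f"{stem}_mask.png")
        meta.append(
            {
                "case_id": stem,
                "abnormality": case.record.abnormality,
                "pathology": case.record.pathology,
                "view": case.record.view,
                "seed": case.params.get("seed"),
                "image": f"{stem}.{ext}",
                "mask": f"{stem}_mask.png",
            }
        )
    pd.DataFrame(meta).to_csv(outdir / "metadata.csv", index=False)
    return outdir / "metadata.csv"
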