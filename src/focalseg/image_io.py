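"""Readers and writers for CT-like slices and binary label masks.

Canonical in-memory forms: slices are ``(H, W, 3)`` uint8 arrays with three
identical channels when the source was grayscale; masks are ``(H, W)`` uint8
grids with values in {0, 1}. DICOM support is optional and requires
``pydicom`` (install the ``focalseg[dicom]`` extra).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from focalseg.errors import FormatError, LabelError, ShapeError

logger = logging.getLogger(__name__)

# Fixed CT lung window in Hounsfield units, available as an alternative to
# the default per-slice min-max scaling.
LUNG_WINDOW_HU = (-1000.0, 400.0)


@dataclass
class SliceRecord:
    image: np.ndarray  # (H, W, 3) uint8
    source_path: Path
    format_tag: str  # "dicom" | "png" | "jpg"


def _to_uint8_minmax(pixels: np.ndarray) -> np.ndarray:
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:  # constant frame: degenerate scaling maps to 0
        return np.zeros(pixels.shape, dtype=np.uint8)
    scaled = (pixels.astype(np.float64) - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def _to_uint8_window(pixels: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    scaled = (np.clip(pixels.astype(np.float64), lo, hi) - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def _read_dicom(path: Path, window: tuple[float, float] | None) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FormatError(
            f"{path}: reading DICOM requires the optional 'pydicom' dependency "
            "(pip install focalseg[dicom])"
        ) from exc
    ds = pydicom.dcmread(str(path))
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept
    if window is not None:
        return _to_uint8_window(pixels, window)
    return _to_uint8_minmax(pixels)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        return "dicom"
    if suffix == ".png":
        return "png"
    if suffix in (".jpg", ".jpeg"):
        return "jpg"
    raise FormatError(f"{path}: unsupported file format '{suffix}'")


def load_slice(
    path: str | Path,
    target_size: int | None = None,
    hu_window: tuple[float, float] | None = None,
) -> SliceRecord:
    """Load a DICOM/PNG/JPG slice into the canonical (H, W, 3) uint8 form.

    DICOM pixel data is windowed to 8 bit (per-slice min-max by default, or a
    fixed HU window if ``hu_window`` is given). Grayscale raster images are
    replicated to three channels. If ``target_size`` is given the image is
    resized to ``target_size x target_size`` (bilinear).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    fmt = _detect_format(path)

    if fmt == "dicom":
        gray = _read_dicom(path, hu_window)
        arr = np.repeat(gray[:, :, None], 3, axis=2)
    else:
        try:
            with Image.open(path) as im:
                im = im.convert("RGB") if im.mode not in ("L", "RGB") else im.copy()
        except Exception as exc:
            raise FormatError(f"{path}: unreadable image ({exc})") from exc
        arr = np.asarray(im, dtype=np.uint8)
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)

    if target_size is not None and arr.shape[:2] != (target_size, target_size):
        if arr.shape[0] != arr.shape[1]:
            logger.warning(
                "%s: non-square input %s resized to %dx%d",
                path, arr.shape[:2], target_size, target_size,
            )
        im = Image.fromarray(arr)
        arr = np.asarray(
            im.resize((target_size, target_size), Image.BILINEAR), dtype=np.uint8
        )
    return SliceRecord(image=arr, source_path=path, format_tag=fmt)


def load_mask(path: str | Path, target_size: int | None = None) -> np.ndarray:
    """Load a binary mask PNG into the canonical {0, 1} uint8 grid.

    Accepts the {0, 255} dialect. Any other value set raises
    :class:`LabelError` listing the offending values.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.uint8)
    values = np.unique(arr)
    if not set(values.tolist()) <= {0, 1} and not set(values.tolist()) <= {0, 255}:
        raise LabelError(
            f"{path}: mask must be binary ({{0,1}} or {{0,255}}), "
            f"found values {values.tolist()}"
        )
    mask = (arr > 0).astype(np.uint8)
    if target_size is not None and mask.shape != (target_size, target_size):
        im = Image.fromarray(mask)
        mask = np.asarray(
            im.resize((target_size, target_size), Image.NEAREST), dtype=np.uint8
        )
    return mask


def check_pair(image: np.ndarray, mask: np.ndarray) -> None:
    """Raise :class:`ShapeError` unless image and mask spatial dims agree."""
    if image.shape[:2] != mask.shape:
        raise ShapeError(
            f"image spatial dims {image.shape[:2]} != mask dims {mask.shape}"
        )


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) or (H, W) uint8 image as PNG."""
    arr = np.asarray(image, dtype=np.uint8)
    Image.fromarray(arr).save(str(path))


def save_mask(mask: np.ndarray, path: str | Path, style: str = "0255") -> None:
    """Write a {0,1} mask as a PNG, either as stored ({0,1}) or scaled to {0,255}."""
    arr = np.asarray(mask, dtype=np.uint8)
    if not set(np.unique(arr).tolist()) <= {0, 1}:
        raise LabelError(f"mask to save must be binary {{0,1}}, got {np.unique(arr)}")
    if style == "0255":
        arr = arr * 255
    elif style != "01":
        raise LabelError(f"unknown mask style '{style}' (use '01' or '0255')")
    Image.fromarray(arr).save(str(path))
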