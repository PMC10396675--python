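"""Per-nodule region extraction from a binary segmentation mask."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage

from focalseg.errors import ShapeError

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class NoduleRegion:
    crop: np.ndarray  # (S, S) uint8 intensity crop, resized
    crop_mask: np.ndarray  # (S, S) uint8 {0,1}, resized nearest-neighbour
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    area_px: int
    centroid: tuple[float, float]
    raw_crop_mask: np.ndarray | None = None  # component mask at native resolution


def extract_nodule_regions(
    image: np.ndarray,
    mask: np.ndarray,
    min_area: int = 9,
    pad: int = 2,
    out_size: int = 64,
) -> list[NoduleRegion]:
    """One fixed-size region per 8-connected mask component of area >= min_area.

    The bounding box is padded by ``pad`` pixels (clipped to the image) and
    the crop resized to ``out_size`` x ``out_size`` (bilinear for intensity,
    nearest-neighbour for the mask so it stays binary).
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    gray = image[:, :, 0] if image.ndim == 3 else image
    if gray.shape != mask.shape:
        raise ShapeError(f"image dims {gray.shape} != mask dims {mask.shape}")
    if not set(np.unique(mask).tolist()) <= {0, 1}:
        raise ShapeError("mask must be binary {0,1}")

    labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONN)
    regions: list[NoduleRegion] = []
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        area = int(comp_mask.sum())
        if area < min_area:
            continue
        rr, cc = np.nonzero(comp_mask)
        r0 = max(int(rr.min()) - pad, 0)
        c0 = max(int(cc.min()) - pad, 0)
        r1 = min(int(rr.max()) + 1 + pad, gray.shape[0])
        c1 = min(int(cc.max()) + 1 + pad, gray.shape[1])
        crop = gray[r0:r1, c0:c1]
        crop_mask = comp_mask[r0:r1, c0:c1].astype(np.uint8)
        crop_rs = np.asarray(
            Image.fromarray(np.asarray(crop, dtype=np.uint8)).resize(
                (out_size, out_size), Image.BILINEAR
            ),
            dtype=np.uint8,
        )
        mask_rs = np.asarray(
            Image.fromarray(crop_mask).resize((out_size, out_size), Image.NEAREST),
            dtype=np.uint8,
        )
        regions.append(
            NoduleRegion(
                crop=crop_rs,
                crop_mask=mask_rs,
                bounding_box=(r0, c0, r1, c1),
                area_px=area,
                centroid=(float(rr.mean()), float(cc.mean())),
                raw_crop_mask=crop_mask,
            )
        )
    return regions
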