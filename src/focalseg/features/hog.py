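"""Histogram of oriented gradients, written out from first principles.

Gradients are central differences with replicated edges; orientation is the
quadrant-aware arctangent folded to [0, 180) under the default unsigned
convention; per-patch histograms use magnitude-weighted soft (linear)
binning between the two nearest bin centres; blocks of patches are
L2-normalised and concatenated in row-major block order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from focalseg.errors import ShapeError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HOGConfig:
    patch_size: int = 4
    n_orientation_bins: int = 9
    signed_orientation: bool = False
    block_size_cells: tuple[int, int] = (2, 2)
    block_norm: str = "L2"  # "L2" | "L2-hys" | "none"
    # the printed-transposed arctan variant (angle of (Gx over Gy)); off by
    # default because it only shifts every orientation by 90 degrees
    transposed_arctan: bool = False

    def __post_init__(self) -> None:
        if self.patch_size < 2:
            raise ValidationError("patch_size must be >= 2")
        if self.n_orientation_bins < 2:
            raise ValidationError("n_orientation_bins must be >= 2")
        if self.block_norm not in ("L2", "L2-hys", "none"):
            raise ValidationError("block_norm must be 'L2', 'L2-hys' or 'none'")


def _as_gray(crop: np.ndarray) -> np.ndarray:
    crop = np.asarray(crop, dtype=np.float64)
    if crop.ndim == 3:
        logger.debug("multi-channel crop converted to luminance for gradients")
        crop = crop.mean(axis=2)
    if crop.ndim != 2:
        raise ShapeError(f"expected a 2-D crop, got ndim={crop.ndim}")
    return crop


def gradients(crop: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients with replicated edges.

    Gx(r, c) = I(r, c+1) - I(r, c-1); Gy(r, c) = I(r+1, c) - I(r-1, c).
    """
    img = _as_gray(crop)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ShapeError(f"crop must be at least 3x3, got {img.shape}")
    padded = np.pad(img, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    return gx, gy


def magnitude_orientation(
    gx: np.ndarray, gy: np.ndarray, cfg: HOGConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gradient magnitude and orientation in degrees.

    Unsigned (default): angles folded into [0, 180). Signed: [0, 360).
    """
    cfg = cfg or HOGConfig()
    gx = np.asarray(gx, dtype=np.float64)
    gy = np.asarray(gy, dtype=np.float64)
    if gx.shape != gy.shape:
        raise ShapeError(f"Gx shape {gx.shape} != Gy shape {gy.shape}")
    magnitude = np.hypot(gx, gy)
    if cfg.transposed_arctan:
        angle = np.degrees(np.arctan2(gx, gy))
    else:
        angle = np.degrees(np.arctan2(gy, gx))
    period = 360.0 if cfg.signed_orientation else 180.0
    return magnitude, np.mod(angle, period)


def _cell_histograms(
    magnitude: np.ndarray, angle: np.ndarray, cfg: HOGConfig
) -> np.ndarray:
    """(n_cells_r, n_cells_c, n_bins) magnitude-weighted soft-binned histograms."""
    period = 360.0 if cfg.signed_orientation else 180.0
    nb = cfg.n_orientation_bins
    bin_width = period / nb
    centers_pos = angle / bin_width  # bin centres at i * width (bin 0 at 0 deg)
    lower = np.floor(centers_pos).astype(int)
    frac = centers_pos - lower
    lo_bin = np.mod(lower, nb)
    hi_bin = np.mod(lower + 1, nb)

    h, w = magnitude.shape
    ps = cfg.patch_size
    ncr, ncc = h // ps, w // ps

    hist = np.zeros((ncr, ncc, nb))
    cell_r = (np.arange(h) // ps)[:, None] * np.ones((1, w), dtype=int)
    cell_c = np.ones((h, 1), dtype=int) * (np.arange(w) // ps)[None, :]
    np.add.at(hist, (cell_r, cell_c, lo_bin), magnitude * (1.0 - frac))
    np.add.at(hist, (cell_r, cell_c, hi_bin), magnitude * frac)
    return hist


def compute_hog(crop: np.ndarray, cfg: HOGConfig | None = None) -> np.ndarray:
    """HOG descriptor of a 2-D crop; length (#blocks) * cells/block * n_bins."""
    cfg = cfg or HOGConfig()
    img = _as_gray(crop)
    ps = cfg.patch_size
    if img.shape[0] % ps or img.shape[1] % ps:
        new_h = int(np.ceil(img.shape[0] / ps)) * ps
        new_w = int(np.ceil(img.shape[1] / ps)) * ps
        logger.warning(
            "crop %s not divisible by patch_size %d; resizing to %dx%d",
            img.shape, ps, new_h, new_w,
        )
        rr = np.clip((np.arange(new_h) * img.shape[0] / new_h).astype(int), 0, img.shape[0] - 1)
        cc = np.clip((np.arange(new_w) * img.shape[1] / new_w).astype(int), 0, img.shape[1] - 1)
        img = img[np.ix_(rr, cc)]

    gx, gy = gradients(img)
    magnitude, angle = magnitude_orientation(gx, gy, cfg)
    cells = _cell_histograms(magnitude, angle, cfg)

    br, bc = cfg.block_size_cells
    ncr, ncc = cells.shape[:2]
    n_blocks_r = max(ncr - br + 1, 1)
    n_blocks_c = max(ncc - bc + 1, 1)
    blocks = []
    for r in range(n_blocks_r):
        for c in range(n_blocks_c):
            block = cells[r : r + br, c : c + bc].ravel()
            if cfg.block_norm in ("L2", "L2-hys"):
                norm = np.sqrt((block ** 2).sum() + 1e-10)
                block = block / norm
                if cfg.block_norm == "L2-hys":
                    block = np.clip(block, None, 0.2)
                    block = block / np.sqrt((block ** 2).sum() + 1e-10)
            blocks.append(block)
    return np.concatenate(blocks)


def hog_length(crop_size: int, cfg: HOGConfig | None = None) -> int:
    """Descriptor length for a square crop of the given side."""
    cfg = cfg or HOGConfig()
    n_cells = crop_size // cfg.patch_size
    br, bc = cfg.block_size_cells
    nbr = max(n_cells - br + 1, 1)
    nbc = max(n_cells - bc + 1, 1)
    return nbr * nbc * br * bc * cfg.n_orientation_bins
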