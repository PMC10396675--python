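"""Local binary patterns: 8-neighbour codes at radius 1.

For each interior pixel the eight neighbours are compared against the
centre; a neighbour at least as bright as the centre contributes its power
of two. Neighbours are visited clockwise starting at the top-left corner,
so codes lie in [0, 255] and a constant patch yields 255 (every difference
is zero and s(0) = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from focalseg.errors import ShapeError, ValidationError

# clockwise from the top-left neighbour: offsets (dr, dc) paired with 2^n
_OFFSETS = [
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
]


@dataclass(frozen=True)
class LBPConfig:
    n_neighbors: int = 8
    radius: int = 1
    normalize: bool = False  # histogram as frequencies instead of counts

    def __post_init__(self) -> None:
        if self.n_neighbors != 8 or self.radius != 1:
            raise ValidationError(
                "only the canonical 8-neighbour, radius-1 pattern is supported"
            )

    @property
    def n_codes(self) -> int:
        return 2 ** self.n_neighbors


def lbp_code(window: np.ndarray) -> int:
    """LBP code of a single 3x3 window (centre pixel vs its 8 neighbours)."""
    window = np.asarray(window, dtype=np.float64)
    if window.shape != (3, 3):
        raise ShapeError(f"expected a 3x3 window, got {window.shape}")
    center = window[1, 1]
    code = 0
    for n, (dr, dc) in enumerate(_OFFSETS):
        if window[1 + dr, 1 + dc] - center >= 0:
            code += 1 << n
    return code


def lbp_image(crop: np.ndarray) -> np.ndarray:
    """(H-2, W-2) grid of LBP codes at every interior pixel (vectorised)."""
    img = np.asarray(crop, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise ShapeError(f"crop must be 2-D and at least 3x3, got {img.shape}")
    center = img[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for n, (dr, dc) in enumerate(_OFFSETS):
        neighbor = img[1 + dr : img.shape[0] - 1 + dr, 1 + dc : img.shape[1] - 1 + dc]
        codes += ((neighbor - center) >= 0).astype(np.int64) << n
    return codes


def compute_lbp(
    crop: np.ndarray, cfg: LBPConfig | None = None, mask: np.ndarray | None = None
) -> np.ndarray:
    """256-bin histogram of LBP codes over all interior pixels.

    If ``mask`` is given, only interior pixels with mask == 1 are counted.
    """
    cfg = cfg or LBPConfig()
    codes = lbp_image(crop)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != np.asarray(crop).shape[:2]:
            raise ShapeError("mask dims must match crop dims")
        codes = codes[mask[1:-1, 1:-1] > 0]
    hist = np.bincount(codes.ravel(), minlength=cfg.n_codes).astype(np.float64)
    if cfg.normalize and hist.sum() > 0:
        hist /= hist.sum()
    return hist
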