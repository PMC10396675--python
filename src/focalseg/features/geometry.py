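"""Geometric lesion descriptor: convex-hull maximum diameter.

The diameter of a pixel set is the largest pairwise Euclidean distance
between its points. Reducing to the convex hull first makes this cheap:
the two farthest points of a set are always hull vertices.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from focalseg.errors import ValidationError


def _max_pairwise(points: np.ndarray) -> float:
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=-1)).max())


def nodule_diameter(mask: np.ndarray) -> float:
    """Max pairwise distance between foreground pixel centres, in pixels.

    A single-pixel mask has diameter 0. Degenerate (collinear) point sets
    fall back to the direct pairwise maximum.
    """
    mask = np.asarray(mask)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise ValidationError("mask has no foreground pixels")
    points = np.column_stack([rr, cc]).astype(np.float64)
    if len(points) == 1:
        return 0.0
    if len(points) <= 3:
        return _max_pairwise(points)
    try:
        hull = ConvexHull(points)
        vertices = points[hull.vertices]
    except QhullError:  # collinear pixel set
        vertices = points
    return _max_pairwise(vertices)


def mask_area(mask: np.ndarray) -> float:
    """Foreground pixel count (optional geometric extra)."""
    return float(np.count_nonzero(np.asarray(mask)))


def mask_perimeter(mask: np.ndarray) -> float:
    """Count of foreground pixels with a 4-neighbour outside the set
    (optional geometric extra)."""
    m = np.asarray(mask).astype(bool)
    padded = np.pad(m, 1)
    boundary = m & ~(
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return float(boundary.sum())
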