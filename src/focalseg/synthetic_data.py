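"""Seeded CT-like phantom slices with ground-truth masks and nodule labels.

Each phantom is a dark background carrying bright structures: nodules
(benign: near-circular discs; malignant: larger, irregular perturbed-radius
blobs) plus elongated vessel-like distractors drawn at the *same* mean
intensity as the nodules, so that intensity alone cannot separate them.
The ground-truth mask marks nodule pixels only; vessels are background.

All randomness derives from ``(spec.seed, slice_index)`` so any slice can be
regenerated independently and bit-identically.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from focalseg.errors import ValidationError

# Nominal LIDC-like scale used to translate the 3-30 mm focal-opacity size
# taxonomy into pixels when a physical diameter is requested.
MM_PER_PIXEL = 0.7

BENIGN = "benign"
MALIGNANT = "malignant"

_MAX_PLACEMENT_RETRIES = 200


@dataclass(frozen=True)
class Nodule:
    """Ground truth for a single rendered nodule."""

    centroid: tuple[float, float]  # (row, col) of the pixel-mass centroid
    diameter: float  # max pairwise distance over the rendered pixels, px
    label: str  # BENIGN or MALIGNANT


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom generator.

    Diameter ranges are in pixels and must not overlap between classes;
    the malignant range must sit strictly above the benign one.
    """

    image_size: int = 128
    n_slices: int = 1
    benign_fraction: float = 103 / 152
    nodule_diameter_range_benign: tuple[float, float] = (5.0, 10.0)
    nodule_diameter_range_malignant: tuple[float, float] = (13.0, 24.0)
    nodules_per_slice: int = 1
    vessel_count: int = 4
    noise_sigma: float = 6.0
    background_intensity: float = 30.0
    structure_intensity: float = 200.0
    mask_format: Literal["01", "0255"] = "0255"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ValidationError("image_size must be >= 32")
        if self.n_slices < 0:
            raise ValidationError("n_slices must be >= 0")
        if not 0.0 <= self.benign_fraction <= 1.0:
            raise ValidationError("benign_fraction must be in [0, 1]")
        for name in ("nodule_diameter_range_benign", "nodule_diameter_range_malignant"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0:
                raise ValidationError(f"{name} must be positive")
            if lo > hi:
                raise ValidationError(f"{name} must satisfy low <= high")
        if self.nodule_diameter_range_malignant[0] <= self.nodule_diameter_range_benign[1]:
            raise ValidationError(
                "nodule_diameter_range_malignant must lie strictly above "
                "nodule_diameter_range_benign"
            )
        if self.nodule_diameter_range_malignant[1] >= self.image_size / 2:
            raise ValidationError(
                "nodule_diameter_range_malignant too large for image_size"
            )
        if self.nodules_per_slice < 0:
            raise ValidationError("nodules_per_slice must be >= 0")
        if self.vessel_count < 0:
            raise ValidationError("vessel_count must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.mask_format not in ("01", "0255"):
            raise ValidationError("mask_format must be '01' or '0255'")


@dataclass
class LabeledSlice:
    """One phantom: image, binary nodule mask, and per-nodule ground truth."""

    image: np.ndarray  # (H, W, 3) uint8, three identical channels
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    nodules: list[Nodule] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.mask.shape:
            raise ValidationError("image and mask spatial dimensions differ")


def _slice_rng(seed: int, slice_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(slice_index)]))


def _render_vessel(canvas: np.ndarray, rng: np.random.Generator, intensity: float) -> None:
    """Draw one elongated capsule (thick segment) onto the canvas in place."""
    size = canvas.shape[0]
    r0 = rng.uniform(0, size, 2)
    angle = rng.uniform(0, np.pi)
    length = rng.uniform(0.35, 0.95) * size
    width = rng.uniform(1.5, 3.5)
    r1 = r0 + length * np.array([np.sin(angle), np.cos(angle)])

    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    d = r1 - r0
    seg_len2 = float(d @ d)
    t = ((rows - r0[0]) * d[0] + (cols - r0[1]) * d[1]) / max(seg_len2, 1e-12)
    t = np.clip(t, 0.0, 1.0)
    dist = np.hypot(rows - (r0[0] + t * d[0]), cols - (r0[1] + t * d[1]))
    inside = dist <= width / 2.0
    canvas[inside] = intensity


def _blob_radius_profile(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random lobulated radius profile r(theta)/r_max in (0, 1], max == 1."""
    theta = np.linspace(0.0, 2 * np.pi, 256, endpoint=False)
    profile = np.zeros_like(theta)
    for k in range(2, 6):
        profile += rng.uniform(0.0, 1.0) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    profile -= profile.min()
    if profile.max() > 0:
        profile /= profile.max()
    # radii span [0.62, 1.0] of the nominal radius -> visibly irregular
    return theta, 0.62 + 0.38 * profile


def _rasterize_nodule(
    size: int,
    center: np.ndarray,
    diameter: float,
    irregular: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean pixel set of one nodule, rescaled so the rendered max pairwise
    extent matches the requested diameter to within about one pixel."""
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    dr, dc = rows - center[0], cols - center[1]
    dist = np.hypot(dr, dc)
    if not irregular:
        return dist <= diameter / 2.0

    theta_tab, profile = _blob_radius_profile(rng)
    angle = np.arctan2(dr, dc) % (2 * np.pi)
    idx = np.minimum((angle / (2 * np.pi) * len(theta_tab)).astype(int), len(theta_tab) - 1)
    radius = diameter / 2.0 * profile[idx]
    inside = dist <= radius
    # one correction pass: rescale so the measured extent matches `diameter`
    measured = _pixel_set_diameter(inside)
    if measured > 0:
        radius *= diameter / measured
        inside = dist <= radius
    return inside


def _pixel_set_diameter(mask: np.ndarray) -> float:
    """Max pairwise Euclidean distance between foreground pixels (convex-hull
    reduction lives in focalseg.features; this local helper only sizes blobs
    during rendering and works on the hull of the boolean set)."""
    from focalseg.features.geometry import nodule_diameter

    if not mask.any():
        return 0.0
    return nodule_diameter(mask)


def generate_slice(spec: PhantomSpec, slice_index: int) -> LabeledSlice:
    """Render one phantom slice deterministically from (spec.seed, slice_index)."""
    if slice_index < 0:
        raise ValidationError("slice_index must be >= 0")
    rng = _slice_rng(spec.seed, slice_index)
    size = spec.image_size

    canvas = np.full((size, size), spec.background_intensity, dtype=np.float64)
    for _ in range(spec.vessel_count):
        _render_vessel(canvas, rng, spec.structure_intensity)

    mask = np.zeros((size, size), dtype=np.uint8)
    nodules: list[Nodule] = []
    placed: list[tuple[np.ndarray, float]] = []
    for _ in range(spec.nodules_per_slice):
        is_benign = rng.random() < spec.benign_fraction
        lo, hi = (
            spec.nodule_diameter_range_benign
            if is_benign
            else spec.nodule_diameter_range_malignant
        )
        diameter = rng.uniform(lo, hi)
        margin = diameter / 2.0 + 3.0
        center = None
        for _attempt in range(_MAX_PLACEMENT_RETRIES):
            cand = rng.uniform(margin, size - margin, 2)
            if all(
                np.hypot(*(cand - c)) > (diameter + d) / 2.0 + 3.0 for c, d in placed
            ):
                center = cand
                break
        if center is None:
            raise ValidationError(
                "could not place nodule without overlap; reduce nodules_per_slice "
                "or diameter ranges"
            )
        placed.append((center, diameter))
        inside = _rasterize_nodule(size, center, diameter, not is_benign, rng)
        canvas[inside] = spec.structure_intensity
        mask[inside] = 1
        rr, cc = np.nonzero(inside)
        nodules.append(
            Nodule(
                centroid=(float(rr.mean()), float(cc.mean())),
                diameter=_pixel_set_diameter(inside),
                label=BENIGN if is_benign else MALIGNANT,
            )
        )

    if spec.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, canvas.shape)
    image8 = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    image = np.repeat(image8[:, :, None], 3, axis=2)
    return LabeledSlice(image=image, mask=mask, nodules=nodules)


MANIFEST_COLUMNS = [
    "slice_id",
    "nodule_id",
    "class",
    "diameter_px",
    "centroid_row",
    "centroid_col",
]


def generate_dataset(spec: PhantomSpec, out_dir: str | Path) -> list[dict]:
    """Write ``spec.n_slices`` phantoms (image + mask PNGs) and a CSV manifest.

    Returns the manifest as a list of row dicts with keys
    ``slice_id,nodule_id,class,diameter_px,centroid_row,centroid_col``.
    """
    from focalseg.image_io import save_image, save_mask

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out}: {exc}") from exc

    rows: list[dict] = []
    for i in range(spec.n_slices):
        sl = generate_slice(spec, i)
        save_image(sl.image, out / f"slice_{i:04d}.png")
        save_mask(sl.mask, out / f"mask_{i:04d}.png", style=spec.mask_format)
        for j, nod in enumerate(sl.nodules):
            rows.append(
                {
                    "slice_id": i,
                    "nodule_id": j,
                    "class": nod.label,
                    "diameter_px": round(nod.diameter, 4),
                    "centroid_row": round(nod.centroid[0], 2),
                    "centroid_col": round(nod.centroid[1], 2),
                }
            )

    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return rows
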