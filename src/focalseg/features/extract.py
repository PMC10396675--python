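"""Turn extracted nodule regions into a fixed-length fused feature table."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from focalseg.features.fusion import FeatureVector, fuse
from focalseg.features.geometry import nodule_diameter
from focalseg.features.hog import HOGConfig, compute_hog
from focalseg.features.lbp import LBPConfig, compute_lbp


def featurize_region(
    crop: np.ndarray,
    crop_mask: np.ndarray,
    true_diameter: float | None = None,
    hog_cfg: HOGConfig | None = None,
    lbp_cfg: LBPConfig | None = None,
    provenance: str = "",
) -> FeatureVector:
    """HOG + LBP on the intensity crop, diameter from the (un-resized) mask.

    ``true_diameter`` lets callers pass the diameter measured on the full
    mask before the crop was resized; otherwise it is measured on
    ``crop_mask``.
    """
    hog = compute_hog(crop, hog_cfg)
    lbp = compute_lbp(crop, lbp_cfg)
    diameter = (
        float(true_diameter)
        if true_diameter is not None
        else (nodule_diameter(crop_mask) if np.any(crop_mask) else 0.0)
    )
    return fuse(hog, lbp, diameter, provenance=provenance)


def feature_table(vectors: list[FeatureVector], labels: list[str]) -> pd.DataFrame:
    """Assemble the classification matrix: nodule_id, label, f_0..f_n."""
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    rows = []
    for vec, label in zip(vectors, labels):
        row = {"nodule_id": vec.provenance, "label": label}
        row.update({f"f_{i}": v for i, v in enumerate(vec.fused)})
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(
    table: pd.DataFrame,
    path: str | Path,
    component_lengths: dict | None = None,
    config: dict | None = None,
) -> None:
    """Write the CSV plus a sidecar JSON schema with component lengths."""
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.10g")
    schema = {
        "n_features": int(table.shape[1] - 2),
        "component_lengths": component_lengths or {},
        "config": config or {},
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=2))
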