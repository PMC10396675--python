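"""Concatenation fusion of the three descriptor families."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from focalseg.errors import ValidationError


@dataclass
class FeatureVector:
    hog: np.ndarray
    lbp_hist: np.ndarray
    geometric: np.ndarray  # (diameter,) by default
    fused: np.ndarray
    provenance: str = ""
    component_lengths: dict = field(default_factory=dict)

    def component(self, name: str) -> np.ndarray:
        """Slice a component back out of the fused vector."""
        start = 0
        for comp in ("hog", "lbp", "geometric"):
            length = self.component_lengths[comp]
            if comp == name:
                return self.fused[start : start + length]
            start += length
        raise KeyError(name)


def fuse(
    hog: np.ndarray,
    lbp_hist: np.ndarray,
    geometric: float | np.ndarray,
    provenance: str = "",
) -> FeatureVector:
    """Concatenate hog || lbp || geometric into one flat descriptor."""
    hog = np.asarray(hog, dtype=np.float64).ravel()
    lbp_hist = np.asarray(lbp_hist, dtype=np.float64).ravel()
    geometric = np.atleast_1d(np.asarray(geometric, dtype=np.float64)).ravel()
    for name, arr in (("hog", hog), ("lbp", lbp_hist), ("geometric", geometric)):
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"non-finite values in component '{name}'")
    fused = np.concatenate([hog, lbp_hist, geometric])
    return FeatureVector(
        hog=hog,
        lbp_hist=lbp_hist,
        geometric=geometric,
        fused=fused,
        provenance=provenance,
        component_lengths={
            "hog": len(hog),
            "lbp": len(lbp_hist),
            "geometric": len(geometric),
        },
    )
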