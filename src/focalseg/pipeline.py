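"""Configured, seeded orchestration of the five pipeline stages.

Stage order: simulate -> train-seg -> segment -> featurize -> classify.
Every stage reads its predecessor's on-disk artifacts, so any stage can be
re-run in isolation; ``run.json`` records the config, derived seeds and
library versions needed to reproduce a run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import focalseg
from focalseg.classification import (
    DEFAULT_BANK,
    EXTENDED_PRESET_BUILDERS,
    PRESET_BUILDERS,
    ClassifierSpec,
    cross_validate,
    rank_and_report,
)
from focalseg.errors import StageError, ValidationError
from focalseg.features.extract import feature_table, featurize_region, write_feature_table
from focalseg.features.geometry import nodule_diameter
from focalseg.features.hog import HOGConfig
from focalseg.features.lbp import LBPConfig
from focalseg.image_io import load_mask, load_slice, save_mask
from focalseg.segmentation import (
    SegNet,
    SegNetConfig,
    TrainConfig,
    build_network,
    extract_nodule_regions,
    predict_mask,
    train,
)
from focalseg.synthetic_data import (
    LabeledSlice,
    Nodule,
    PhantomSpec,
    generate_dataset,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train-seg", "segment", "featurize", "classify")


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass(frozen=True)
class RegionConfig:
    min_area: int = 9
    pad: int = 2
    out_size: int = 64

    def __post_init__(self) -> None:
        if self.min_area < 1 or self.pad < 0 or self.out_size < 8:
            raise ValidationError("invalid region extraction parameters")


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    hog: HOGConfig = field(default_factory=HOGConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    region: RegionConfig = field(default_factory=RegionConfig)
    classifiers: tuple[str, ...] = tuple(DEFAULT_BANK)
    k_folds: int = 10
    featurize_source: str = "predicted"  # or "truth"
    standardize_features: bool = True

    def __post_init__(self) -> None:
        valid = set(PRESET_BUILDERS) | set(EXTENDED_PRESET_BUILDERS)
        for name in self.classifiers:
            if name not in valid:
                raise ValidationError(f"unknown classifier '{name}' in roster")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if self.featurize_source not in ("predicted", "truth"):
            raise ValidationError("featurize_source must be 'predicted' or 'truth'")


_SECTION_TYPES = {
    "phantom": PhantomSpec,
    "train": TrainConfig,
    "hog": HOGConfig,
    "lbp": LBPConfig,
    "region": RegionConfig,
}
_SCALAR_KEYS = {
    "seed": int,
    "log_level": str,
    "classifiers": list,
    "k_folds": int,
    "featurize_source": str,
    "standardize_features": bool,
}


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a validated PipelineConfig from a plain dict; unknown keys fail."""
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    known = set(_SECTION_TYPES) | set(_SCALAR_KEYS)
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")

    kwargs: dict = {}
    for key, cls in _SECTION_TYPES.items():
        if key not in raw:
            continue
        section = raw[key]
        if not isinstance(section, dict):
            raise ValidationError(f"config section '{key}' must be a mapping")
        valid_fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(section) - valid_fields
        if bad:
            raise ValidationError(f"unknown keys in '{key}': {sorted(bad)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
        }
        kwargs[key] = cls(**coerced)
    for key, typ in _SCALAR_KEYS.items():
        if key in raw:
            value = raw[key]
            if typ is not list and not isinstance(value, typ):
                raise ValidationError(
                    f"config key '{key}' must be {typ.__name__}, got {type(value).__name__}"
                )
            kwargs[key] = tuple(value) if key == "classifiers" else value

    # stage seeds derive from the global seed unless explicitly pinned
    seed = kwargs.get("seed", 0)
    if "phantom" in kwargs and "seed" not in raw.get("phantom", {}):
        kwargs["phantom"] = dataclasses.replace(
            kwargs["phantom"], seed=derive_stage_seed(seed, "simulate")
        )
    elif "phantom" not in kwargs:
        kwargs["phantom"] = PhantomSpec(seed=derive_stage_seed(seed, "simulate"))
    if "train" in kwargs and "seed" not in raw.get("train", {}):
        kwargs["train"] = dataclasses.replace(
            kwargs["train"], seed=derive_stage_seed(seed, "train-seg")
        )
    elif "train" not in kwargs:
        kwargs["train"] = TrainConfig(seed=derive_stage_seed(seed, "train-seg"))
    return PipelineConfig(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse + default + cross-check a YAML/JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file {path} does not exist")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    return config_from_dict(raw)


def config_to_dict(config: PipelineConfig) -> dict:
    return dataclasses.asdict(config)


# --------------------------------------------------------------------------
# stage implementations (each reads/writes disk artifacts)
# --------------------------------------------------------------------------


def load_dataset(data_dir: str | Path) -> tuple[list[LabeledSlice], pd.DataFrame]:
    """Rebuild LabeledSlices from a generated dataset directory."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.csv"
    if not manifest_path.exists():
        raise ValidationError(f"no manifest.csv in {data_dir}")
    manifest = pd.read_csv(manifest_path)
    slices = []
    slice_ids = sorted({int(p.stem.split("_")[1]) for p in data_dir.glob("slice_*.png")})
    for sid in slice_ids:
        image = load_slice(data_dir / f"slice_{sid:04d}.png").image
        mask = load_mask(data_dir / f"mask_{sid:04d}.png")
        nodules = [
            Nodule(
                centroid=(row.centroid_row, row.centroid_col),
                diameter=row.diameter_px,
                label=row["class"],
            )
            for _, row in manifest[manifest.slice_id == sid].iterrows()
        ]
        slices.append(LabeledSlice(image=image, mask=mask, nodules=nodules))
    return slices, manifest


def stage_simulate(config: PipelineConfig, run_dir: Path) -> Path:
    data_dir = run_dir / "data"
    generate_dataset(config.phantom, data_dir)
    return data_dir


def stage_train_seg(config: PipelineConfig, run_dir: Path, data_dir: Path) -> Path:
    slices, _ = load_dataset(data_dir)
    size = config.phantom.image_size
    net = build_network(
        SegNetConfig(input_size=(size, size, 3), seed=derive_stage_seed(config.seed, "net-init"))
    )
    result = train(net, slices, config.train)
    model_dir = run_dir / "model"
    model_dir.mkdir(parents=True, exist_ok=True)
    net.save(model_dir / "segnet.npz")
    pd.DataFrame(result.history).to_csv(model_dir / "history.csv", index=False)
    (model_dir / "val_metrics.json").write_text(
        json.dumps(result.val_metrics.as_dict(), indent=2)
    )
    (model_dir / "split.json").write_text(
        json.dumps({"train": result.train_indices, "test": result.test_indices})
    )
    return model_dir


def stage_segment(config: PipelineConfig, run_dir: Path, data_dir: Path, model_dir: Path) -> Path:
    model_path = model_dir / "segnet.npz"
    if not model_path.exists():
        raise ValidationError(f"no trained model at {model_path}")
    net = SegNet.load(model_path)
    pred_dir = run_dir / "pred_masks"
    pred_dir.mkdir(parents=True, exist_ok=True)
    for img_path in sorted(Path(data_dir).glob("slice_*.png")):
        sid = int(img_path.stem.split("_")[1])
        record = load_slice(img_path)
        mask = predict_mask(net, record.image)
        save_mask(mask, pred_dir / f"mask_{sid:04d}.png", style=config.phantom.mask_format)
    return pred_dir


def _match_label(
    centroid: tuple[float, float], manifest_rows: pd.DataFrame, max_dist: float
) -> str | None:
    if manifest_rows.empty:
        return None
    d = np.hypot(
        manifest_rows.centroid_row.to_numpy() - centroid[0],
        manifest_rows.centroid_col.to_numpy() - centroid[1],
    )
    i = int(d.argmin())
    if d[i] > max_dist:
        return None
    return str(manifest_rows.iloc[i]["class"])


def stage_featurize(
    config: PipelineConfig, run_dir: Path, data_dir: Path, mask_dir: Path
) -> Path:
    """Extract per-nodule fused features; labels come from the manifest by
    nearest-centroid matching (unmatched regions are dropped and logged)."""
    data_dir, mask_dir = Path(data_dir), Path(mask_dir)
    if not mask_dir.exists():
        raise ValidationError(f"mask directory {mask_dir} does not exist")
    _, manifest = load_dataset(data_dir)
    vectors, labels = [], []
    n_dropped = 0
    for img_path in sorted(data_dir.glob("slice_*.png")):
        sid = int(img_path.stem.split("_")[1])
        mask_path = mask_dir / f"mask_{sid:04d}.png"
        if not mask_path.exists():
            raise ValidationError(f"missing mask for slice {sid}: {mask_path}")
        image = load_slice(img_path).image
        mask = load_mask(mask_path)
        regions = extract_nodule_regions(
            image,
            mask,
            min_area=config.region.min_area,
            pad=config.region.pad,
            out_size=config.region.out_size,
        )
        rows = manifest[manifest.slice_id == sid]
        for j, region in enumerate(regions):
            label = _match_label(
                region.centroid, rows, max_dist=config.phantom.image_size * 0.15
            )
            if label is None:
                n_dropped += 1
                continue
            vectors.append(
                featurize_region(
                    region.crop,
                    region.crop_mask,
                    true_diameter=nodule_diameter(region.raw_crop_mask),
                    hog_cfg=config.hog,
                    lbp_cfg=config.lbp,
                    provenance=f"slice{sid:04d}_n{j}",
                )
            )
            labels.append(label)
    if n_dropped:
        logger.warning("featurize: dropped %d regions with no manifest match", n_dropped)
    if not vectors:
        raise ValidationError("featurize produced no labelled regions")
    table = feature_table(vectors, labels)
    features_dir = run_dir / "features"
    features_dir.mkdir(parents=True, exist_ok=True)
    write_feature_table(
        table,
        features_dir / "features.csv",
        component_lengths=vectors[0].component_lengths,
        config={"hog": dataclasses.asdict(config.hog), "lbp": dataclasses.asdict(config.lbp)},
    )
    return features_dir


def stage_classify(config: PipelineConfig, run_dir: Path, features_dir: Path) -> Path:
    features_path = Path(features_dir) / "features.csv"
    if not features_path.exists():
        raise ValidationError(f"no features.csv at {features_path}")
    table = pd.read_csv(features_path)
    X = table.drop(columns=["nodule_id", "label"]).to_numpy(dtype=np.float64)
    y = table["label"].to_numpy()
    specs = [
        ClassifierSpec(name, seed=derive_stage_seed(config.seed, "classify"))
        for name in config.classifiers
    ]
    report = cross_validate(
        X,
        y,
        specs,
        k_folds=config.k_folds,
        seed=derive_stage_seed(config.seed, "classify"),
        standardize=config.standardize_features,
    )
    results_dir = run_dir / "results"
    rank_and_report(report, results_dir)
    return results_dir


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages in order; abort on the first failing stage."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config_text = json.dumps(config_to_dict(config), sort_keys=True, default=str)
    run_info = {
        "config": config_to_dict(config),
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "stage_seeds": {s: derive_stage_seed(config.seed, s) for s in STAGES},
        "versions": {
            "focalseg": focalseg.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "stages_completed": [],
    }

    def _run(stage: str, fn, *args):
        try:
            out = fn(config, run_dir, *args)
        except Exception as exc:
            run_info["failed_stage"] = stage
            (run_dir / "run.json").write_text(json.dumps(run_info, indent=2, default=str))
            raise StageError(stage, str(exc)) from exc
        run_info["stages_completed"].append(stage)
        return out

    data_dir = _run("simulate", stage_simulate)
    model_dir = _run("train-seg", stage_train_seg, data_dir)
    pred_dir = _run("segment", stage_segment, data_dir, model_dir)
    mask_dir = data_dir if config.featurize_source == "truth" else pred_dir
    features_dir = _run("featurize", stage_featurize, data_dir, mask_dir)
    _run("classify", stage_classify, features_dir)

    (run_dir / "run.json").write_text(json.dumps(run_info, indent=2, default=str))
    return run_dir
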