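# focalseg

Segmentation and benign/malignant classification of lung focal opacities
(3–30 mm nodules) on CT-like slices, built as a five-stage pipeline:

1. **synthetic_data** — seeded CT-like phantom generator: bright nodules
   (benign = near-circular, malignant = larger, lobulated) among vessel-like
   distractors at the *same* intensity, with ground-truth masks and
   per-nodule labels.
2. **image_io** — DICOM/PNG/JPG slice readers (DICOM needs the optional
   `pydicom` extra), binary-mask I/O in the `{0,1}` and `{0,255}` dialects.
3. **segmentation** — a 14-layer encoder–decoder pixel-classification
   network (3 conv+ReLU, max-pool, conv+ReLU, 4×4/stride-2 transposed conv
   with 1-px crop, 1×1 conv, softmax, pixel-classification loss) implemented
   in pure numpy with exact backprop; five-metric mask scoring (global/mean
   accuracy, mean/weighted IoU, boundary-F1); per-nodule region extraction.
4. **features** — from-scratch HOG (4×4 patches, 9 unsigned bins, block-L2),
   8-neighbour LBP (256-bin histogram), convex-hull maximum diameter, and
   concatenation fusion `hog ‖ lbp ‖ diameter`.
5. **classification** — a 17-preset classifier bank (trees, polynomial and
   Gaussian SVMs, KNN variants, bagged/subspace/RUSBoost ensembles) under
   stratified 10-fold cross-validation with pooled out-of-fold confusion
   reporting (accuracy, sensitivity, specificity, FPR, error rate, timing);
   positive class = malignant.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the six acceptance criteria (operator–oracle
equivalence, metric identities, network contracts, desk-scale learning,
end-to-end label recovery, determinism); the desk-scale training test takes
a couple of minutes on one CPU.

## CLI

Every stage is a subcommand of `focalseg`; all accept `--config cfg.yaml`,
`--seed N` (overrides the global seed) and `--out DIR`:

```bash
focalseg simulate  --n-slices 60 --seed 1 --out run/           # phantoms + masks + manifest
focalseg train-seg --config cfg.yaml --data run/data --out run/
focalseg segment   --config cfg.yaml --model run/model --data run/data --out run/
focalseg featurize --config cfg.yaml --data run/data --masks run/pred_masks --out run/
focalseg classify  --config cfg.yaml --features run/features --folds 10 --out run/
focalseg run-all   --config cfg.yaml --seed 1 --out run/       # all five stages
```

A config file is a YAML mapping with sections `phantom`, `train`, `hog`,
`lbp`, `region` plus scalars `seed`, `classifiers`, `k_folds`,
`featurize_source` (`predicted` or `truth`), `standardize_features`;
unknown keys are rejected. A single global `seed` deterministically derives
every stage seed, and `run.json` in the output directory records config
hash, seeds and versions. Example:

```yaml
seed: 1
phantom: {image_size: 128, n_slices: 60, vessel_count: 4}
train: {epochs: 10, learning_rate: 0.05}
k_folds: 10
```

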