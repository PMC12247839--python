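# bonesep

Automated joint-space detection and individual-bone separation for 3D
micro-CT volumes of multi-bone structures (e.g. rodent paws), with a
built-in synthetic phantom generator and a per-bone segmentation audit.

The pipeline mirrors a classical + learned enhancement chain:

1. **HU windowing** (default 2500–20000 HU) to get the bone mask.
2. **Joint-space enhancement**: black top-hat, multi-scale Hessian
   dark-sheet filtering, and stick tensor voting; responses are binarized
   (Otsu by default), unioned, and grown by a half-kernel-2 dilation.
3. **Optional learned prediction**: a 3D U-Net with a ResNet-18-style
   residual encoder (implemented on a small numpy autodiff engine — no GPU
   or external NN framework needed) predicts the peri-articular negative
   space; tiled, non-overlapping inference handles arbitrarily large
   volumes seam-free.
4. **Separation**: markers = connected components of (bone ∧ ¬joint);
   a deterministic marker-based watershed (numba priority flood over the
   negated distance transform) expands markers to the bone borders.
5. **Evaluation**: per-bone outcomes (correct / over-split /
   over-connected / missing), accuracy = (TP+TN)/(TP+TN+FP+FN)·100 with
   TN ≡ 0, and per-compartment summaries.

All arrays are `(z, y, x)`; spacing is carried in micrometres.

## CLI

```bash
# generate synthetic phantoms with ground-truth labels
bonesep phantom --out phantoms/ --count 3 --seed 0

# batch-segment every volume in a directory (classical-only)
bonesep segment phantoms/ --out results/
# ... with a trained joint model
bonesep segment scans/ --out results/ --model model/model.npz

# train the joint-space predictor from (volume, *_labels) pairs
bonesep train phantoms/ --out model/ --epochs 50

# audit a predicted label map against ground truth
bonesep evaluate results/phantom_000_labels.nii phantoms/phantom_000_labels.nii \
    --table phantoms/phantom_000_table.csv --out eval
```

`segment` reads NIfTI / multi-page TIFF / MHA files and DICOM series
directories, and emits per-dataset label + joint-mask NIfTIs, a JSON run
log (stage timings, voxel counts, full realized config) and a batch
`summary.csv`. Exit codes: 0 ok, 1 total failure, 2 partial failure.
Pipeline parameters live in a YAML config (`--config`); unknown keys are
rejected. Identical config + seed reruns are byte-identical.

## Layout

```
src/bonesep/
  volume_io.py     # Volume3D/LabelVolume/BoneTable, NIfTI/TIFF/MHA/DICOM I/O, HU windowing
  phantom.py       # PhantomSpec -> synthetic paw-like volumes + exact truth, fusion/erosion
  enhancement.py   # black top-hat, Hessian sheetness, tensor voting, response combination
  joint_model/     # joint-truth derivation, tiles, autodiff engine, 3D U-Net, training, tiling
  separation.py    # markers, numba watershed, run_pipeline
  evaluation.py    # label matching, outcome taxonomy, accuracy, compartment summaries
  config.py, cli.py
tests/             # pytest suite; oracles.py holds brute-force references
scripts/acceptance.py
```
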