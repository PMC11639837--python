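# hsidefect

Toolkit for classifying visually similar, blood-related surface defects
(classes `CBC`, `CBB`, `CBBR`) on hyperspectral images:

- **hypercube** — ENVI-style cube I/O (BSQ/BIL/BIP), black/white reflectance
  calibration `R = (I − B)/(W − B)`, pseudo-color synthesis from three bands,
  region spectrum extraction, JSON / Pascal-VOC box annotations.
- **synthgen** — synthetic labeled spectra and annotated scenes with
  hemoglobin-like absorption features (420–600 nm) and a water feature near
  962 nm, so every downstream stage is testable without proprietary data.
- **spectral_net** — a 1-D CNN spectral classifier (faithful preset: 13 conv /
  5 max-pool / 2 fully-connected layers; scaled preset for coarse grids),
  implemented on a small NumPy layer library with seeded, bit-reproducible
  training.
- **firefly_select** — discrete firefly search over k-band combinations with
  the classifier's validation score as luminance (defaults n=5, k=3,
  β0=0.5, γ=0.8, α=0.6, 100 iterations), memoized evaluations, and a
  random-search baseline.
- **fusion_detect** — one-stage single-scale and two-stage RPN detectors on
  pseudo-color renderings, plus a fusion head that re-classifies each
  localized box from concatenated 2-D region features and 1-D spectral
  features extracted from the cube.
- **eval_metrics** — IoU, greedy matching, precision/recall/F1 (harmonic
  mean), PR curves and AP (all-point or 11-point interpolation), mAP,
  mIoU (per-image), confusion matrices, and a table-style report.

## CLI

```bash
hsidefect simulate      --config demo.yaml --seed 1 --out sim/
hsidefect correct       --raw raw.hdr --black black.hdr --white white.hdr --out corrected.hdr
hsidefect select-bands  --data sim/spectra.csv --out selection.json --iterations 100
hsidefect train-spectral --data sim/spectra.csv --out spectral_model
hsidefect train-detector --scenes sim/ --bands 5,18,53 --out detector
hsidefect detect        --model detector --scene scene.hdr --out detections.json
hsidefect evaluate      --detections detections.json --truths truths.json --out report.json
hsidefect run-all       --config demo.yaml --seed 1 --out run/
```

`run-all` executes the whole workflow (simulate → select bands → train
spectral classifier → train detector → detect → evaluate) into a run
directory with a manifest (config hash, seed, versions); reruns with the
same config and seed are bit-identical, and `--resume` skips completed
stages. A minimal `demo.yaml`:

```yaml
grid: desk
n_bands_desk: 60
n_spectra_per_class: 300
n_train_scenes: 24
n_test_scenes: 8
firefly:
  max_iterations: 15
  objective: {epochs: 8}
detector:
  epochs: 40
  fusion: true
```

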