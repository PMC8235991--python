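# dermopt

Dermoscopy lesion analysis pipeline with metaheuristic feature selection:

1. **denoise** — non-local means filtering (patch-similarity weighted averaging,
   Gaussian patch kernel, reflect padding),
2. **segment** — Otsu between-class-variance thresholding, hole filling,
   opening/closing, largest-component extraction,
3. **features** — 16 intensity / co-occurrence-texture / region-shape
   descriptors per image,
4. **mteo** — Thermal Exchange Optimization and its modified variant
   (opposition-based learning + sinusoidal chaotic map) as a general
   box-constrained minimizer,
5. **selection** — wrapper feature selection: the optimizer searches subsets
   scored by the Matthews correlation of a cross-validated SVM,
6. **classify** — RBF-SVM classification with the repeated stratified 85/15
   holdout protocol and five confusion-based metrics,
7. **benchmarks** — eight classic test functions and a TEO-vs-MTEO multi-run
   comparison harness,
8. **synthetic** — lesion-image and planted-signal tabular generators so the
   whole pipeline is testable without any external database.

## Command-line usage

```bash
# write a synthetic cohort (PNGs + truth masks + manifest.csv)
dermo-synth --n 40 --preset easy --seed 0 --out data/

# full pipeline: denoise -> segment -> features -> selection -> SVM holdout
dermo-pipeline run --manifest data/manifest.csv --out results/run1

# one optimizer run on a named benchmark function
mteo-run --objective F1 --dim 30 --pop 100 --iters 200 --seed 0

# the multi-run benchmark comparison table (min/std of final bests)
mteo-bench --functions F1,F4,F6,F7 --runs 35 --pop 100 --iters 200 --out bench.csv
```

Pipeline stage parameters (denoise strength and radii, structuring element
shape, selection budget, SVM settings, seeds) live in a YAML config passed
via `--config`; the effective configuration is written next to every run's
outputs so reruns are reproducible.

## Notes

- Images are converted to grayscale (luma weights) and resized to 256×256
  on load; all processing is single-channel with intensities in [0, 1].
- The texture descriptors are computed on a normalized symmetric gray-level
  co-occurrence matrix (32 levels, displacement (0, 1) by default).
- The optimizer is a pure minimizer; the selection stage negates the
  Matthews correlation so that better subsets have lower cost.
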