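# microgliamorph

Segmentation, morphometry and phenotype classification of microglia in
brightfield (dark-cells-on-light) tissue images, with a ground-truthed
synthetic data generator so the whole pipeline is testable without any
image downloads.

The pipeline:

1. **segmentation** — CLAHE + inversion, top-hat/Gaussian soma enhancement
   with Otsu thresholding and a 1,500-px size filter, hybrid process
   detection (local adaptive segmentation of the image and of its
   Hessian-ridge-filtered version), endpoint-to-soma bridging within 50 px,
   orphan/border clearing, and parallel flood fill into uniquely labeled
   single-cell extracts (cell/soma/process masks + process skeleton).
2. **morphometry** — 18 per-cell parameters: areas, perimeters, convex-hull
   metrics, solidity/convexity/circularity, skeleton length/branch
   points/endpoints, process count (3-px soma dilation rule), and Sholl
   analysis derivatives (branching index, critical radius, dendritic
   maximum, Schoenen ramification index), plus per-image segmented-area %
   and cell density per mm².
3. **cnn_classify** — a four-class VGG-16-style CNN (13 conv / 5 max-pool /
   2 FC / 4-node softmax; conv → ReLU → BatchNorm; Adam, lr 0.001, batch 64,
   dropout 0.5) on 128×128 tri-level cell masks, with a `reduced` preset
   (input 64, width factor 1/8) that trains in minutes on one CPU. The
   backend is pure NumPy — no deep-learning framework is required.
4. **nc_compare** — nearest-centroid classification over morphometric
   parameter subsets (per-class median centroids), degree of conformity
   against the CNN labels, exact symmetry tests for the 4×4 cross-tabs,
   exhaustive subset sweeps (131,054 subsets of sizes 2–17 over the 17
   always-defined parameters) and Spearman correlation analyses.
5. **synthetic_data** — generative phenotype archetypes (amoeboid,
   activated, rod-like, ramified) with known soma/process/skeleton ground
   truth; tissue-like tiles and labeled classifier datasets.
6. **pipeline_cli** — batch orchestration, class-percentage summaries,
   color-coded overlays (ramified blue, rod-like orange, activated red,
   amoeboid gray) and the `microgliamorph` command line.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes a scaled-down CNN training run and an end-to-end
segmentation→classification test; expect a few minutes on one CPU.

## CLI

```sh
# generate synthetic fixtures
microgliamorph synth make-tiles --n 5 --size 768 --seed 0 --out tiles/
microgliamorph synth make-dataset --n-per-class 100 --seed 0 --out dataset/

# train the reduced CNN on the synthetic dataset, then run the pipeline
microgliamorph train --out model --n-per-class 400 --seed 42
microgliamorph segment --in 'tiles/*.tif' --out seg_out/
microgliamorph classify --in 'tiles/tile_000.tif' --checkpoint model --out out/

# conformity sweep and class-percentage report over per-cell CSVs
microgliamorph compare --cells out/tile_000_cells.csv --out compare/
microgliamorph report --cells out/tile_000_cells.csv --out report.csv
```

Per-image outputs: label TIFF, per-cell CSV (18 parameters + CNN label +
class probabilities), color overlay PNG, and a batch `manifest.json` with
per-stage counts.

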