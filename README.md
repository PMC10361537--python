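# scihc — sequential chromogenic IHC image cytometry

Sequential chromogenic immunohistochemistry (scIHC) stains, images and
strips one biomarker per round on a *single* tissue section, producing a
stack of whole-slide RGB images — one hematoxylin counterstain reference
plus one AEC (3-amino-9-ethylcarbazole, red-magenta) chromogen image per
marker. Turning that stack into single-cell data requires solving, in
order: per-round tissue shifts and micro-deformations, slide-quality
artifacts, nucleus segmentation, per-cell chromogen quantification,
subset gating, and spatial statistics. `scihc` implements that full
pipeline for researchers doing tissue cytometry on chromogenic panels
(the bundled examples use an eight-marker lymph-node immune panel), plus
a synthetic-slide simulator so every stage is verifiable against known
ground truth without patient material.

## What the pipeline computes

1. **Tiling** — images are processed on a grid of 512×512 px chunks with
   a mean-pooled multiresolution pyramid.
2. **Registration** — each marker round is aligned to the hematoxylin
   reference: a global rigid shift maximizing normalized
   cross-correlation (NCC) at downsampled resolution, chunkwise NCC
   template matching for correspondence-point candidates, pruning of
   candidates whose displacement deviates from the local
   m-nearest-neighbor componentwise median by more than a tolerance,
   and natural-neighbor (Sibson) interpolation of the accepted residual
   displacements into a dense distortion field
   `d(x, y) = Σᵢ wᵢ(x, y) dᵢ`, where the weights are Voronoi-cell
   overlap areas (exact at every support point).
3. **Masking** — rule-based artifact masks (folds, out-of-focus areas,
   red blood cells) and a tissue-of-interest ROI (largest connected
   tissue component minus artifacts); externally computed masks can be
   dropped in through the same interface.
4. **Segmentation** — color deconvolution in optical-density space
   (`OD_c = −log(I_c / I0_c)`, least-squares projection onto unit stain
   vectors) separates hematoxylin from AEC; nuclei are segmented in the
   hematoxylin channel by marker-controlled watershed.
5. **Cytometry** — for every cell and round, the mean AEC amount over
   the nuclear mask ∩ ROI (out-of-bounds warp sentinels excluded);
   export as FCS 3.1 + CSV; threshold gating into named subsets
   (default panel: plasmablast CD138⁺, pDC BDCA2⁺, cDC1 CD141⁺CD1c⁻,
   cDC2 CD141⁻CD1c⁺, sinusoidal macrophage CD169⁺, non-sinusoidal
   macrophage CD169⁻CD68⁺, NK CD56⁺, granulocyte CD66b⁺).
6. **Spatial analysis** — per query cell, the median Euclidean
   center-to-center distance to its k = 5 nearest target-subset cells;
   the contact fraction at a 10 µm threshold (reported both on the
   median-of-5 statistic and on the single nearest neighbor); and an
   abundance-preserving permutation null with empirical
   `p = (1 + #{null ≥ observed}) / (B + 1)`.

## Worked example

Simulate an eight-marker slide and run the full pipeline:

```bash
scihc simulate --out demo --seed 3
scihc run --config demo/run.yaml
```

On the default synthetic slide (1024×1024 px at 0.5 µm/px, 800 nuclei)
this prints, among the stage summaries:

```
"segmentation": {"n_cells": 814, ...}
"cytometry":    {"n_cells": 814, "n_excluded": 0}
"gating": {"plasmablast": 86, "pDC": 81, "cDC1": 70, "cDC2": 78,
           "sinusoidal_macrophage": 73, "non_sinusoidal_macrophage": 70,
           "NK": 78, "granulocyte": 77}
```

814 nuclei were segmented (800 planted; a few bright noise blobs split),
and the gated counts match the planted 10% phenotype frequencies. The
exported `analysis/cells.csv` holds one row per cell:

```
 id    x_um     y_um  area_px    CD138    BDCA2    CD141     CD1c   ...
  1 211.469 111.0200      176 0.031502 0.037802 0.034722 0.034295  ...
  3 180.922 216.6030      174 0.743894 0.032022 0.032904 0.031585  ...
```

Cell 3 is a plasmablast: its CD138 mean optical-density amount (0.74)
sits far above the negative background (~0.03), which is why a single
gate threshold separates the populations cleanly. The spatial report
`analysis/spatial/plasmablast_vs_pDC.json` gives, for this unstructured
slide, a nearest-neighbor contact fraction of 0.058 at 10 µm with
permutation p = 0.73 — i.e. no more plasmablast–pDC contact than
abundance alone predicts, as expected when phenotypes are placed at
random.

The same stages are available as composable subcommands
(`simulate`, `register`, `mask`, `segment`, `measure`, `gate`,
`spatial`, `run`) reading and writing PNG/TIFF, CSV, FCS and JSON, and
as library functions (`scihc.register_round`, `scihc.segment_nuclei`,
`scihc.neighbor_statistic`, ...).

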