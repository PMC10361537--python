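# Methods

This note documents the models, defaults and numerical choices behind
`scihc`, what the synthetic-slide simulator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Image model

All stages share one convention: 0-based pixel coordinates, `x` =
column, `y` = row, origin top-left; physical distances are
`px × mpp` (microns per pixel). A displacement `(dx, dy)` always maps
reference coordinates into a round's frame: tissue at reference
`(x, y)` is found at `(x + dx, y + dy)` in the moving image, and
warping samples the moving image at exactly those coordinates.

Chromogenic stains absorb light multiplicatively, so both the simulator
and the deconvolution work in optical-density space:
`OD_c = −log(max(I_c, 1) / I0_c)` per RGB channel, with per-pixel stain
amounts the least-squares projection of the OD triple onto unit stain
vectors, clamped at zero. The simulator renders with the same
Beer–Lambert mixture, so deconvolution on synthetic data is exact up to
quantization — which is precisely what lets gating recovery be tested
against planted phenotypes. Default stain directions are the standard
hematoxylin vector (0.651, 0.701, 0.290) and an AEC-like vector
(0.274, 0.680, 0.680); both are configuration, not measured facts, and
the simulator writes its own vectors into the run config so analyses of
synthetic bundles are self-consistent.

## Synthetic slides

The simulator emulates a densely cellularized lymph-node region scanned
at 20X:

- **Scale**: 0.5 µm/px default. The scanner resolution of the source
  material this pipeline targets is not standardized, so `mpp` is a
  config value.
- **Nuclei**: anti-aliased filled ellipses; 70% round
  (lymphocyte-like, 10–14 px ≈ 5–7 µm across) and 30% elongated
  (macrophage-like, axis ratio 1.8–3). Dart-throwing placement enforces
  a minimum center separation equal to the major axis of the larger
  nucleus, so nuclei never overlap and segmentation ground truth is
  unambiguous; impossible packings raise after a bounded number of
  retries.
- **Phenotypes**: independent Bernoulli draws per marker (default
  frequency 0.1), stored as 0/1 columns of the ground-truth table.
  `plant_contacts` additionally repositions target-positive cells next
  to query-positive cells until a requested contact fraction holds,
  moving only targets that currently provide no contact and preferring
  positions that keep the no-overlap separation.
- **Deformation**: each round carries a rigid shift (magnitude ≤
  `max_shift`, default 25 px) plus a sum of Gaussian radial bumps
  (default 8 bumps, σ ≈ 300 px) rescaled so the sampled magnitude bound
  equals `field_amplitude` (default 12 px). The field `G` is defined
  over reference coordinates; the round image is rendered by
  numerically inverting `r + G(r) = u` (fixed-point iteration on a
  stride-4 grid, bilinear upsampling), so `G(center)` is an *exact*
  truth value for registration recovery, not an approximation.
- **Artifacts**: darkened fold bands, Gaussian-blurred discs, and
  repainted non-tissue margins, each with an exact truth mask.
- **Noise**: additive Gaussian, default sd 3 intensity units (~1% of
  range).

Not emulated: staining chemistry (carryover, stripping, antigen
retrieval), cytoplasm/membrane signal, nucleus overlap, chromatin
texture, illumination gradients, and scanner compression. Passing tests
therefore demonstrate the pipeline's *contracts* — alignment recovery,
mask geometry, segmentation of non-overlapping convex nuclei,
measurement and gating arithmetic, spatial statistics — not performance
on real histology, where segmentation in particular would need a
trained model plugged in through the label-image adapter.

## Registration

Defaults: rigid search at 1/16 resolution with full-resolution
refinement within ±16 px; correspondence templates 128×128 on a 256-px
chunk grid with a 64-px search radius; candidates gated by NCC ≥ 0.5
and template variance ≥ 1e-4 of the intensity range squared; pruning
with m = 8 neighbors and 10 px tolerance. NCC peaks are refined to
subpixel precision by parabolic fit. Registration runs on luminance;
chromogen-heavy regions are not masked out (hematoxylin texture
dominates the correlation).

The correspondence grid spacing of 256 px (rather than the 512-px
storage tile) is deliberate: the distortion field varies on a ~300 px
scale, and anchors every 512 px under-resolve it (interpolation error
scales with spacing², ~4× worse), while 256-px spacing holds the mean
recovery error at cell centers well under 2 px on full-size synthetic
rounds. Templates are cut from the *reference* chunk center and
searched in the moving image, so each measured displacement is anchored
exactly at its stored reference coordinate.

Pruning iterates the median-deviation rule to a fixed point: a point is
removed when its displacement deviates from the componentwise median of
its m nearest surviving candidates by more than the tolerance, and the
pass repeats until nothing changes. A single pass is not idempotent
(removals shift the neighbor medians); the fixed-point version is, by
construction, and still satisfies the per-point rejection rule on its
output. Points with fewer than m neighbors are kept so sparse tissue
edges do not lose all anchors.

The distortion field is a natural-neighbor (Sibson) interpolant:
weights are the areas a query point's inserted Voronoi cell steals from
each support's cell, computed exactly by convex-polygon clipping
(candidate neighbors from the Delaunay circumcircle test). Inside the
support hull this is exact at supports and continuous; outside the
hull the nearest support's displacement is used; with fewer than three
(or collinear) supports the field degrades gracefully to clamped 1-D
linear interpolation along the principal axis. Dense warping evaluates
the exact interpolant on a 16-px raster and looks it up bilinearly —
the smooth fields this pipeline corrects lose nothing measurable at
that stride, and accuracy-critical evaluations (support exactness,
cell-center errors) always use the exact path. Warped samples that fall
outside the moving frame become NaN, the sentinel every downstream
mean excludes.

## Masking

All thresholds are configuration (0–255 luminance scale): background
above 238; folds below luminance 100 inside tissue, closed with a
6-px disk, minimum area 400 px; out-of-focus regions where the local
variance of the Laplacian (25-px window) falls below 8% of the median
tissue sharpness — fine texture and shot noise survive in focus and
vanish under blur, making this measure nearly bimodal; RBC-like pixels
where `R − (G+B)/2 > 60`. The ROI is the largest connected non-background
component, hole-filled, minus all artifact masks; an empty ROI is an
error. Masks are computed once on the hematoxylin reference and applied
to all rounds after alignment — one geometry for the series.

## Segmentation and cytometry

Watershed baseline: Gaussian smoothing (σ = 1.5) of the hematoxylin
amount channel, Otsu threshold (or fixed), hole filling, Euclidean
distance transform, peak markers at ≥ 7 px separation, watershed, area
filter 30–5000 px. Centroids are unweighted pixel means (whether the
source pipeline intensity-weighted them is unknown; unweighted is the
simpler convention and is stated here so it can be changed knowingly).
The nuclear mask is the measurement region — no cytoplasm ring.

Cells whose fraction of invalid pixels (outside ROI, or NaN from
warping) exceeds 25% are flagged excluded and dropped from FCS export;
the threshold is configurable and deliberately conservative. FCS files
are version 3.1, list mode, little-endian float32, parameters
`X_um, Y_um` then one per marker; `$PnN` names are sanitized to
alphanumerics/underscore with the original kept in `$PnS`. Gate
thresholds are always user-supplied (an Otsu-based helper exists but is
never the default): reproducibility over convenience.

## Spatial statistics

The per-cell statistic is the median distance to the k = 5 nearest
target cells, center to center in µm; a cell in both sets never pairs
with itself; with fewer than k admissible targets the median of all
available distances is used and the count recorded. Neighbor search
uses a k-d tree for candidate selection but recomputes the selected
distances with plain `hypot`, so results equal an all-pairs brute-force
computation bit for bit — the accelerated path is exact, not
approximate.

The contact fraction (threshold 10 µm) is reported on both the
median-of-5 statistic and the single nearest-neighbor distance: a
"fraction of cells within 10 µm" can legitimately mean either, so both
are always emitted rather than guessing. A planted contact (one target
within radius) is by construction a nearest-neighbor property, so
recovery checks use the nearest-neighbor version.

The abundance null redraws the target subset (size preserved)
uniformly from all non-query cells B times (default 999) and recomputes
the contact fraction; `p = (1 + #{null ≥ observed}) / (B + 1)` is never
exactly zero and is valid for any B ≥ 1. Histogram bins are right-open,
width 5 µm, purely presentational.

## Problem sizes and determinism

The test suite and acceptance script run synthetic slides at
1024–2048 px with 500–3000 nuclei — large enough that chunk grids,
pruning, field fitting and spatial statistics all operate in their
intended regime, small enough to iterate on quickly. Every stage is a
pure function of (inputs, config, seed); per-component generators are
derived from the seed with fixed offsets, so identical seeds give
byte-identical CSV/FCS outputs, which the tests assert literally.

## Known limitations

- The watershed baseline assumes mostly convex, non-touching nuclei;
  real densely packed tissue needs a learned segmenter via the adapter.
- Rigid alignment is translation-only by default; slide rotation
  between rounds is assumed negligible (an optional coarse rotation
  search is out of scope for v1).
- Natural-neighbor evaluation cost grows with support count (polygon
  clipping per query); for very dense correspondence grids the raster
  stride, not the exact path, should be the dense-warp workhorse (it
  already is by default).
- Artifact rules are tuned to the simulator's appearance model; on real
  slides their thresholds are starting points, and the mask-provider
  interface is the intended path for learned masks.
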