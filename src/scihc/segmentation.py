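"""Stain separation and nucleus segmentation.

Chromogenic stains mix multiplicatively in transmitted light, so the
per-pixel optical density ``OD_c = -log(I_c / I0_c)`` is (to first
order) a non-negative linear combination of per-stain unit absorbance
vectors. `deconvolve_stains` inverts that mixture by least squares,
yielding a hematoxylin amount channel (used for nucleus segmentation)
and an AEC amount channel (the red-magenta chromogen quantified per
cell by the cytometry module).

Nuclei are segmented in the hematoxylin reference with a classical
marker-controlled watershed: smoothing, thresholding, hole filling,
distance transform, peak markers, watershed split, and an area filter.
A learned segmenter can replace this baseline by supplying its label
image through the same `LabelImage` contract (`segment_nuclei` is just
one provider).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature, filters, measure, segmentation as sk_seg

import pandas as pd

from scihc.synthetic import AEC_OD, HEMATOXYLIN_OD


@dataclass
class StainModel:
    """Unit RGB absorbance directions of the stains plus the
    per-channel background (unstained) intensity I0."""

    vectors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"hematoxylin": HEMATOXYLIN_OD, "aec": AEC_OD}
    )
    background: tuple[float, float, float] = (255.0, 255.0, 255.0)

    def matrix(self) -> np.ndarray:
        """(3, n_stains) matrix of unit column vectors."""
        cols = []
        for name, v in self.vectors.items():
            a = np.asarray(v, dtype=np.float64)
            n = np.linalg.norm(a)
            if n == 0:
                raise ValueError(f"zero stain vector for {name!r}")
            cols.append(a / n)
        m = np.column_stack(cols)
        if np.linalg.matrix_rank(m) < m.shape[1]:
            raise ValueError("stain vectors are linearly dependent")
        return m

    @property
    def names(self) -> list[str]:
        return list(self.vectors)


def deconvolve_stains(
    rgb: np.ndarray, model: StainModel | None = None
) -> dict[str, np.ndarray]:
    """Per-stain amount channels from an RGB image.

    ``OD_c = -log(max(I_c, 1) / I0_c)``; per-pixel amounts are the
    least-squares projection of the OD triple onto the stain vectors,
    clamped at zero. NaN pixels (out-of-bounds sentinels from warping)
    propagate to NaN amounts.
    """
    model = model or StainModel()
    m = model.matrix()
    img = np.asarray(rgb, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    i0 = np.asarray(model.background, dtype=np.float64)
    if np.any(i0 <= 0):
        raise ValueError("background intensity I0 must be > 0")
    nan_mask = np.isnan(img).any(axis=2)
    od = -np.log(np.maximum(np.nan_to_num(img, nan=1.0), 1.0) / i0)
    # least-squares: amounts = (M^T M)^-1 M^T od
    pinv = np.linalg.pinv(m)
    amounts = od.reshape(-1, 3) @ pinv.T
    amounts = np.clip(amounts, 0.0, None).reshape(img.shape[0], img.shape[1], -1)
    out = {}
    for k, name in enumerate(model.names):
        ch = amounts[..., k]
        ch[nan_mask] = np.nan
        out[name] = ch
    return out


def reconstruct_rgb(amounts: dict[str, np.ndarray], model: StainModel | None = None) -> np.ndarray:
    """Beer-Lambert recomposition of stain amounts back to RGB."""
    model = model or StainModel()
    m = model.matrix()
    stack = np.stack([amounts[name] for name in model.names], axis=-1)
    od = stack @ m.T
    i0 = np.asarray(model.background, dtype=np.float64)
    return i0 * np.exp(-od)


@dataclass
class SegmentationParams:
    smooth_sigma: float = 1.5
    threshold: float | None = None       # None: Otsu on the OD channel
    min_peak_distance: int = 7           # px between watershed markers
    min_area: int = 30                   # px
    max_area: int = 5000                 # px


def segment_nuclei(
    hematoxylin: np.ndarray,
    roi: np.ndarray | None = None,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Marker-controlled watershed segmentation of the hematoxylin
    amount channel; returns a label image (0 = background, labels are
    contiguous positive integers), restricted to ``roi``."""
    params = params or SegmentationParams()
    ch = np.nan_to_num(np.asarray(hematoxylin, dtype=np.float64), nan=0.0)
    if roi is not None:
        ch = np.where(roi, ch, 0.0)
    sm = ndimage.gaussian_filter(ch, params.smooth_sigma)
    if params.threshold is None:
        fg_vals = sm[sm > 1e-6]
        if fg_vals.size == 0:
            return np.zeros(ch.shape, dtype=np.int32)
        thr = filters.threshold_otsu(sm)
    else:
        thr = params.threshold
    fg = sm > thr
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        return np.zeros(ch.shape, dtype=np.int32)

    dist = ndimage.distance_transform_edt(fg)
    peaks = feature.peak_local_max(
        dist, min_distance=params.min_peak_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(ch.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    if markers.max() == 0:
        return np.zeros(ch.shape, dtype=np.int32)
    labels = sk_seg.watershed(-dist, markers, mask=fg, connectivity=1)

    # area filter + relabel to contiguous ids
    out = np.zeros_like(labels)
    next_id = 1
    for region in measure.regionprops(labels):
        if params.min_area <= region.area <= params.max_area:
            out[labels == region.label] = next_id
            next_id += 1
    return out


def label_to_cells(labels: np.ndarray, mpp: float) -> pd.DataFrame:
    """Geometry table from a label image: one row per cell with its
    unique id, pixel-mean centroid in px and um, and area in px."""
    if mpp <= 0:
        raise ValueError("mpp must be > 0")
    labels = np.asarray(labels)
    cols = ["id", "x_px", "y_px", "x_um", "y_um", "area_px"]
    if labels.max() == 0:
        return pd.DataFrame({c: pd.Series(dtype="float64") for c in cols}).astype(
            {"id": "int64", "area_px": "int64"}
        )
    regions = measure.regionprops(labels)
    rows = []
    for r in regions:
        cy, cx = r.centroid  # (row, col) = (y, x)
        rows.append((r.label, cx, cy, cx * mpp, cy * mpp, int(r.area)))
    df = pd.DataFrame(rows, columns=cols)
    return df.astype({"id": "int64", "area_px": "int64"}).sort_values("id", ignore_index=True)
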