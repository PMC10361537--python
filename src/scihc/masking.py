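"""Artifact and tissue-of-interest masks.

Rule-based detectors for the slide-quality problems that corrupt
quantification — tissue folds (dark compressed bands), out-of-focus
areas (locally flat texture), red blood cells (strongly red-dominant
pixels) — plus a tissue-of-interest mask that keeps the largest
connected tissue component and subtracts every artifact. These rules
stand in for learned segmenters; `MaskProvider` lets externally
computed masks (e.g. from a trained network) be dropped in unchanged.

Masks are computed once on the hematoxylin reference round and applied
to all rounds after alignment (one geometry for the whole series).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from scipy import ndimage
from skimage import morphology

from scihc.image import SlideImage, as_gray

ARTIFACT_LABELS = ("fold", "out_of_focus", "rbc")


@dataclass
class MaskingRules:
    """Thresholds of the rule-based artifact detectors.

    All values are implementation choices (config), expressed on the
    0-255 intensity scale of the RGB input.
    """

    background_luminance: float = 238.0   # above: not tissue
    fold_luminance: float = 100.0         # below (inside tissue): fold
    fold_min_area: int = 400              # px; drops nucleus-sized blobs
    fold_close_radius: int = 6
    focus_window: int = 25                # px, local-variance window
    focus_rel_threshold: float = 0.08     # fraction of median tissue sharpness
    focus_min_area: int = 2000
    rbc_red_dominance: float = 60.0       # R - (G + B)/2 above: RBC-like
    rbc_min_area: int = 30
    roi_close_radius: int = 8


class MaskProvider(Protocol):
    """Anything that can supply named masks for a reference image."""

    def __call__(self, image: SlideImage) -> dict[str, np.ndarray]: ...


def _local_variance(gray: np.ndarray, window: int) -> np.ndarray:
    mean = ndimage.uniform_filter(gray, window)
    mean_sq = ndimage.uniform_filter(gray * gray, window)
    return np.maximum(mean_sq - mean * mean, 0.0)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(labels, keep)


def detect_artifacts(
    image: SlideImage, rules: MaskingRules | None = None
) -> dict[str, np.ndarray]:
    """Detect folds, out-of-focus areas and red blood cells.

    Returns independent boolean masks keyed by label. Each detector is
    restricted to tissue (non-background luminance), morphologically
    cleaned, and filtered by a minimum area so that isolated nuclei or
    noise specks do not register as artifacts.
    """
    rules = rules or MaskingRules()
    rgb = image.pixels.astype(np.float64)
    lum = image.luminance()
    tissue = lum <= rules.background_luminance

    # folds: dark bands inside tissue
    fold = tissue & (lum < rules.fold_luminance)
    if rules.fold_close_radius:
        fold = morphology.closing(fold, morphology.disk(rules.fold_close_radius))
    fold = _remove_small(fold, rules.fold_min_area)

    # out of focus: low local sharpness (variance of the Laplacian —
    # fine texture and shot noise survive in focus, vanish under blur)
    sharp = _local_variance(ndimage.laplace(lum), rules.focus_window)
    tissue_sharp = sharp[tissue & ~fold]
    oof = np.zeros_like(tissue)
    if tissue_sharp.size:
        thr = rules.focus_rel_threshold * float(np.median(tissue_sharp))
        oof = tissue & ~fold & (sharp < thr)
        oof = morphology.closing(oof, morphology.disk(5))
        oof = _remove_small(oof, rules.focus_min_area)

    # red blood cells: strong red dominance
    red_dom = rgb[..., 0] - 0.5 * (rgb[..., 1] + rgb[..., 2])
    rbc = tissue & (red_dom > rules.rbc_red_dominance)
    rbc = _remove_small(rbc, rules.rbc_min_area)

    return {"fold": fold, "out_of_focus": oof, "rbc": rbc}


def tissue_roi_mask(
    image: SlideImage,
    artifact_masks: dict[str, np.ndarray] | None = None,
    rules: MaskingRules | None = None,
) -> np.ndarray:
    """Tissue-of-interest mask: non-background pixels, largest connected
    component (which drops detached margins of foreign tissue), minus
    all artifact masks. Raises when no foreground tissue exists."""
    rules = rules or MaskingRules()
    lum = image.luminance()
    tissue = lum <= rules.background_luminance
    if rules.roi_close_radius:
        tissue = morphology.closing(tissue, morphology.disk(rules.roi_close_radius))
    labels, n = ndimage.label(tissue)
    if n == 0:
        raise ValueError("no tissue foreground found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    roi = labels == (1 + int(np.argmax(sizes)))
    roi = ndimage.binary_fill_holes(roi)
    for mask in (artifact_masks or {}).values():
        roi &= ~mask
    if not roi.any():
        raise ValueError("tissue ROI is empty after artifact subtraction")
    return roi
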