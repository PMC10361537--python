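"""Synthetic-slide simulator.

Generates multi-round RGB images of a nucleated tissue region with a
hematoxylin-like counterstain and an AEC-like red-magenta chromogen on
phenotype-positive cells, together with full ground truth: cell centers
and shapes, per-marker phenotypes, per-round rigid shifts plus smooth
bounded non-rigid deformation fields, and artifact masks. Every
downstream stage (registration, masking, segmentation, cytometry,
spatial statistics) is testable against this ground truth without any
patient data.

Rendering uses Beer-Lambert mixing in optical-density space: the RGB
intensity at a pixel is ``I_c = I0_c * exp(-OD_c)`` where the optical
density is a non-negative combination of unit stain vectors (the same
model the segmentation module inverts by color deconvolution).

Deformation model: each staining round carries a global rigid shift and
a smooth field equal to a sum of Gaussian radial bumps, rescaled so the
maximum sampled magnitude equals ``field_amplitude``. The field ``G``
is defined over *reference* coordinates — tissue at reference position
``(x, y)`` appears at ``(x + dx, y + dy)`` in the round image — so the
true displacement at any cell center is simply ``G(center)``, an exact
oracle for registration recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from scihc.image import SlideImage

# Default stain absorbance directions (unit RGB optical-density triples).
# Hematoxylin is the standard blue-purple counterstain vector; the
# AEC-like vector absorbs green/blue, giving the red-magenta chromogen.
HEMATOXYLIN_OD = (0.651, 0.701, 0.290)
AEC_OD = (0.2743, 0.6796, 0.6803)

DEFAULT_PANEL = ("CD138", "BDCA2", "CD141", "CD1c", "CD169", "CD68", "CD56", "CD66b")

HEMATOXYLIN = "hematoxylin"


def _unit(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(v, dtype=np.float64)
    return a / np.linalg.norm(a)


@dataclass
class SimConfig:
    """Parameters of the synthetic slide.

    Geometry is in pixels; ``mpp`` converts to microns. Defaults emulate
    a densely cellularized lymph-node region scanned at 20X
    (0.5 um/px): round lymphocyte-like nuclei ~5-7 um across plus a
    fraction of elongated macrophage-like nuclei with axis ratio up to
    3, per-round shifts of up to ``max_shift`` px and micro-deformations
    bounded by ``field_amplitude`` px.
    """

    width: int = 1024
    height: int = 1024
    mpp: float = 0.5
    n_cells: int = 800
    round_fraction: float = 0.7          # remainder are elongated nuclei
    round_diameter: tuple[float, float] = (10.0, 14.0)   # px, full axis
    elongated_minor: tuple[float, float] = (7.0, 9.0)    # px, full axis
    elongated_ratio: tuple[float, float] = (1.8, 3.0)    # major/minor
    markers: tuple[str, ...] = DEFAULT_PANEL
    phenotype_frequencies: dict[str, float] = field(default_factory=dict)
    default_frequency: float = 0.1
    hematoxylin_rgb: tuple[float, float, float] = HEMATOXYLIN_OD
    aec_rgb: tuple[float, float, float] = AEC_OD
    background: tuple[int, int, int] = (245, 245, 243)
    tissue_od: float = 0.06              # faint neutral absorbance of tissue
    hem_strength: tuple[float, float] = (0.85, 1.05)  # per-cell OD range
    aec_strength: tuple[float, float] = (0.75, 0.95)
    noise_sd: float = 3.0                # additive Gaussian, intensity units
    max_shift: float = 25.0              # px, rigid shift magnitude bound
    field_amplitude: float = 12.0        # px, non-rigid magnitude bound
    field_smoothness: float = 300.0      # px, Gaussian bump sigma
    n_bumps: int = 8
    tissue_margin: float = 0.06          # frame fraction left cell-free
    artifacts: tuple[dict, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ValueError("mpp must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.field_amplitude < 0:
            raise ValueError("field_amplitude must be >= 0")
        for m, f in self.phenotype_frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"phenotype frequency for {m} not in [0, 1]")
        if not 0.0 <= self.default_frequency <= 1.0:
            raise ValueError("default_frequency not in [0, 1]")

    def frequency(self, marker: str) -> float:
        return self.phenotype_frequencies.get(marker, self.default_frequency)

    def tissue_ellipse(self) -> tuple[float, float, float, float]:
        """(cx, cy, semi_x, semi_y) of the tissue region."""
        cx, cy = self.width / 2.0, self.height / 2.0
        sx = self.width * (0.5 - self.tissue_margin)
        sy = self.height * (0.5 - self.tissue_margin)
        return cx, cy, sx, sy


@dataclass
class BumpField:
    """Sum of Gaussian radial bumps; smooth, bounded, exactly evaluable.

    ``G(p) = scale * sum_j a_j * exp(-|p - c_j|^2 / (2 sigma_j^2))``
    with ``scale`` chosen so the magnitude sampled on a stride-2 grid
    equals the configured amplitude bound (with a small safety margin).
    """

    centers: np.ndarray     # (n, 2) as (x, y)
    amps: np.ndarray        # (n, 2) as (dx, dy)
    sigmas: np.ndarray      # (n,)
    scale: float = 1.0

    def __call__(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        dx = np.zeros(np.broadcast(x, y).shape)
        dy = np.zeros_like(dx)
        for (cx, cy), (ax, ay), s in zip(self.centers, self.amps, self.sigmas):
            w = np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * s * s))
            dx += ax * w
            dy += ay * w
        return self.scale * dx, self.scale * dy

    def to_dict(self) -> dict:
        return {
            "centers": self.centers.tolist(),
            "amps": self.amps.tolist(),
            "sigmas": self.sigmas.tolist(),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BumpField":
        return cls(
            centers=np.asarray(d["centers"], dtype=np.float64).reshape(-1, 2),
            amps=np.asarray(d["amps"], dtype=np.float64).reshape(-1, 2),
            sigmas=np.asarray(d["sigmas"], dtype=np.float64).ravel(),
            scale=float(d["scale"]),
        )

    @classmethod
    def zero(cls) -> "BumpField":
        return cls(np.zeros((0, 2)), np.zeros((0, 2)), np.zeros(0), 0.0)


@dataclass
class GroundTruth:
    """Simulator truth for one synthetic slide.

    ``cells`` has one row per nucleus: ``id``, center ``x``/``y`` (px),
    ``major_axis``/``minor_axis`` (px, full lengths), ``orientation``
    (radians), per-cell stain strengths ``hem_od``/``aec_od``, and one
    0/1 phenotype column per configured marker.
    """

    cells: pd.DataFrame
    per_round_shift: dict[int, tuple[float, float]]
    per_round_field: dict[int, BumpField]
    artifact_masks: dict[str, np.ndarray]
    config: SimConfig
    seed: int

    def phenotype(self, marker: str) -> np.ndarray:
        if marker not in self.config.markers:
            raise KeyError(f"unknown marker {marker!r}")
        return self.cells[marker].to_numpy().astype(bool)

    def round_index(self, marker: str) -> int:
        return self.config.markers.index(marker)

    def true_displacement(
        self, round_index: int, x: np.ndarray, y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Total (rigid + non-rigid) displacement at reference coords."""
        sx, sy = self.per_round_shift[round_index]
        fx, fy = self.per_round_field[round_index](x, y)
        return sx + fx, sy + fy


def _place_nuclei(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Dart-throwing placement inside the tissue ellipse.

    Minimum center separation between two nuclei is the major axis of
    the larger one, which keeps segmentation ground truth unambiguous
    (no overlapping nuclei by construction).
    """
    n = cfg.n_cells
    cx0, cy0, sx, sy = cfg.tissue_ellipse()

    n_round = int(round(n * cfg.round_fraction))
    is_round = np.zeros(n, dtype=bool)
    is_round[:n_round] = True
    rng.shuffle(is_round)

    major = np.empty(n)
    minor = np.empty(n)
    d = rng.uniform(*cfg.round_diameter, size=n)
    mn = rng.uniform(*cfg.elongated_minor, size=n)
    ratio = rng.uniform(*cfg.elongated_ratio, size=n)
    major[is_round] = d[is_round]
    minor[is_round] = d[is_round]
    major[~is_round] = (mn * ratio)[~is_round]
    minor[~is_round] = mn[~is_round]
    orientation = np.where(is_round, 0.0, rng.uniform(0.0, math.pi, size=n))

    xs = np.empty(n)
    ys = np.empty(n)
    placed = 0
    tries = 0
    max_tries = 400 * max(n, 1)
    # keep the whole ellipse footprint inside the tissue region
    pad = major / 2.0 + 1.0
    while placed < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n} nuclei without overlap after {max_tries} "
                "tries; reduce n_cells or nucleus sizes"
            )
        tries += 1
        u = rng.uniform(-1.0, 1.0)
        v = rng.uniform(-1.0, 1.0)
        if u * u + v * v > 1.0:
            continue
        x = cx0 + u * (sx - pad[placed])
        y = cy0 + v * (sy - pad[placed])
        if placed:
            dist = np.hypot(xs[:placed] - x, ys[:placed] - y)
            sep = np.maximum(major[:placed], major[placed])
            if np.any(dist < sep):
                continue
        xs[placed] = x
        ys[placed] = y
        placed += 1

    cells = pd.DataFrame(
        {
            "id": np.arange(1, n + 1, dtype=np.int64),
            "x": xs,
            "y": ys,
            "major_axis": major,
            "minor_axis": minor,
            "orientation": orientation,
            "hem_od": rng.uniform(*cfg.hem_strength, size=n),
            "aec_od": rng.uniform(*cfg.aec_strength, size=n),
        }
    )
    for marker in cfg.markers:
        cells[marker] = (rng.random(n) < cfg.frequency(marker)).astype(np.int8)
    return cells


def _make_field(cfg: SimConfig, rng: np.random.Generator) -> BumpField:
    if cfg.field_amplitude <= 0 or cfg.n_bumps == 0:
        return BumpField.zero()
    centers = np.column_stack(
        [
            rng.uniform(0, cfg.width, size=cfg.n_bumps),
            rng.uniform(0, cfg.height, size=cfg.n_bumps),
        ]
    )
    angles = rng.uniform(0, 2 * math.pi, size=cfg.n_bumps)
    mags = rng.uniform(0.3, 1.0, size=cfg.n_bumps)
    amps = np.column_stack([mags * np.cos(angles), mags * np.sin(angles)])
    sigmas = np.full(cfg.n_bumps, cfg.field_smoothness) * rng.uniform(
        0.7, 1.3, size=cfg.n_bumps
    )
    fld = BumpField(centers, amps, sigmas, scale=1.0)
    ys, xs = np.mgrid[0 : cfg.height : 2, 0 : cfg.width : 2]
    dx, dy = fld(xs.astype(float), ys.astype(float))
    mx = float(np.max(np.hypot(dx, dy)))
    if mx == 0.0:
        return BumpField.zero()
    fld.scale = 0.995 * cfg.field_amplitude / mx
    return fld


def generate_ground_truth(config: SimConfig) -> GroundTruth:
    """Generate cells, phenotypes, per-round deformations and masks.

    Deterministic under ``config.seed``; raises if the requested number
    of nuclei cannot be packed without center overlap.
    """
    rng = np.random.default_rng([config.seed, 0x5C1])
    cells = _place_nuclei(config, rng)

    shifts: dict[int, tuple[float, float]] = {}
    fields: dict[int, BumpField] = {}
    for r, _marker in enumerate(config.markers):
        ang = rng.uniform(0, 2 * math.pi)
        mag = rng.uniform(0.4, 1.0) * config.max_shift
        shifts[r] = (mag * math.cos(ang), mag * math.sin(ang))
        fields[r] = _make_field(config, rng)

    return GroundTruth(
        cells=cells,
        per_round_shift=shifts,
        per_round_field=fields,
        artifact_masks={},
        config=config,
        seed=config.seed,
    )


def plant_contacts(
    gt: GroundTruth,
    query_marker: str,
    target_marker: str,
    fraction: float,
    radius_um: float,
) -> GroundTruth:
    """Reposition target-positive cells so that at least
    ``ceil(fraction * n_query)`` query-positive cells have a
    target-positive cell within ``radius_um`` (center to center).

    Only the repositioned target cells move; everything else is
    untouched. Used to plant a known spatial contact fraction that the
    full pipeline must recover.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    for m in (query_marker, target_marker):
        if m not in gt.config.markers:
            raise KeyError(f"unknown marker {m!r}")
    if fraction == 0.0:
        return gt

    cfg = gt.config
    cells = gt.cells.copy()
    radius_px = radius_um / cfg.mpp
    q_idx = np.flatnonzero(cells[query_marker].to_numpy() == 1)
    t_idx = np.flatnonzero(cells[target_marker].to_numpy() == 1)
    if len(t_idx) == 0 or len(q_idx) == 0:
        raise ValueError("both markers need at least one positive cell")

    xy = cells[["x", "y"]].to_numpy()
    need = math.ceil(fraction * len(q_idx))

    def has_contact(qi: int) -> bool:
        others = t_idx[t_idx != qi]
        if len(others) == 0:
            return False
        d = np.hypot(xy[others, 0] - xy[qi, 0], xy[others, 1] - xy[qi, 1])
        return bool(np.any(d <= radius_px))

    satisfied = {qi for qi in q_idx if has_contact(qi)}
    missing = [qi for qi in q_idx if qi not in satisfied]
    rng = np.random.default_rng([gt.seed, 0xC07AC7])
    rng.shuffle(missing)
    if need > len(satisfied):
        # movable targets: target-positive, not themselves query cells, and
        # not currently within radius of any query (so no existing contact
        # is broken by moving them)
        q_set = set(q_idx.tolist())

        def provides_contact(ti: int) -> bool:
            d = np.hypot(xy[q_idx, 0] - xy[ti, 0], xy[q_idx, 1] - xy[ti, 1])
            d = d[q_idx != ti]
            return bool(np.any(d <= radius_px))

        movable = [ti for ti in t_idx if ti not in q_set and not provides_contact(ti)]
        rng.shuffle(movable)
        cx0, cy0, sx, sy = cfg.tissue_ellipse()
        major = cells["major_axis"].to_numpy()
        queue = list(missing)
        while len(satisfied) < need:
            queue = [qi for qi in queue if qi not in satisfied]
            if not queue:
                break
            if not movable:
                raise ValueError(
                    "not enough movable target-positive cells to plant the "
                    "requested contact fraction"
                )
            qi = queue.pop(0)
            ti = movable.pop()
            # prefer positions inside the contact radius that also keep
            # the no-overlap separation to every other nucleus
            for attempt in range(200):
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0.72, 0.95) * radius_px
                nx = xy[qi, 0] + rad * math.cos(ang)
                ny = xy[qi, 1] + rad * math.sin(ang)
                if ((nx - cx0) / sx) ** 2 + ((ny - cy0) / sy) ** 2 >= 0.96:
                    continue
                dist = np.hypot(xy[:, 0] - nx, xy[:, 1] - ny)
                dist[ti] = np.inf
                if attempt == 199 or np.all(dist >= np.maximum(major, major[ti])):
                    break
            xy[ti] = (nx, ny)
            cells.loc[cells.index[ti], ["x", "y"]] = (nx, ny)
            satisfied.add(qi)
            # a moved target may serve other nearby query cells too
            for qj in queue:
                if np.hypot(nx - xy[qj, 0], ny - xy[qj, 1]) <= radius_px:
                    satisfied.add(qj)
        if len(satisfied) < need:
            raise ValueError(
                "could not satisfy the requested contact fraction"
            )

    return replace(gt, cells=cells)


def _ellipse_coverage(
    cfg: SimConfig, cells: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Anti-aliased per-pixel coverage (0..1) of each nucleus, summed.

    Values stay <= 1 in practice because centers never come closer than
    the larger major axis.
    """
    cov = np.zeros((cfg.height, cfg.width), dtype=np.float64)
    per_cell = np.empty(len(cells), dtype=object)
    for i, row in enumerate(cells.itertuples(index=False)):
        a = row.major_axis / 2.0
        b = row.minor_axis / 2.0
        ca, sa = math.cos(row.orientation), math.sin(row.orientation)
        r = math.ceil(a) + 2
        x0 = max(int(row.x) - r, 0)
        x1 = min(int(row.x) + r + 1, cfg.width)
        y0 = max(int(row.y) - r, 0)
        y1 = min(int(row.y) + r + 1, cfg.height)
        if x0 >= x1 or y0 >= y1:
            per_cell[i] = (x0, y0, np.zeros((0, 0)))
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx = xs - row.x
        dy = ys - row.y
        u = (dx * ca + dy * sa) / a
        v = (-dx * sa + dy * ca) / b
        q = np.sqrt(u * u + v * v)
        # ~1 px anti-aliased edge in the short-axis direction
        edge = 1.0 / min(a, b)
        c = np.clip((1.0 - q) / edge + 0.5, 0.0, 1.0)
        cov[y0:y1, x0:x1] += c
        per_cell[i] = (x0, y0, c)
    return cov, per_cell


def _marker_rng(cfg: SimConfig, marker: str) -> np.random.Generator:
    idx = 1 + cfg.markers.index(marker) if marker != HEMATOXYLIN else 0
    return np.random.default_rng([cfg.seed, 0x4E0D, idx])


def render_round(gt: GroundTruth, marker: str, config: SimConfig | None = None) -> SlideImage:
    """Render one staining round in the (undeformed) reference frame.

    Every nucleus gets the hematoxylin-like counterstain; cells positive
    for ``marker`` additionally carry the AEC-like chromogen. Passing
    the reserved name ``"hematoxylin"`` renders the counterstain-only
    reference. Additive Gaussian noise at the configured sd.
    """
    cfg = config or gt.config
    if marker != HEMATOXYLIN and marker not in cfg.markers:
        raise KeyError(f"unknown marker {marker!r}")

    hem_amt = np.zeros((cfg.height, cfg.width), dtype=np.float64)
    aec_amt = np.zeros_like(hem_amt)
    if len(gt.cells):
        _, per_cell = _ellipse_coverage(cfg, gt.cells)
        positive = (
            gt.phenotype(marker) if marker != HEMATOXYLIN else np.zeros(len(gt.cells), bool)
        )
        hem = gt.cells["hem_od"].to_numpy()
        aec = gt.cells["aec_od"].to_numpy()
        for i in range(len(gt.cells)):
            x0, y0, c = per_cell[i]
            if c.size == 0:
                continue
            h, w = c.shape
            hem_amt[y0 : y0 + h, x0 : x0 + w] += hem[i] * c
            if positive[i]:
                aec_amt[y0 : y0 + h, x0 : x0 + w] += aec[i] * c

    cx0, cy0, sx, sy = cfg.tissue_ellipse()
    ys, xs = np.mgrid[0 : cfg.height, 0 : cfg.width]
    in_tissue = ((xs - cx0) / sx) ** 2 + ((ys - cy0) / sy) ** 2 <= 1.0

    hem_vec = _unit(cfg.hematoxylin_rgb)
    aec_vec = _unit(cfg.aec_rgb)
    od = (
        hem_amt[..., None] * hem_vec
        + aec_amt[..., None] * aec_vec
        + (in_tissue[..., None] * cfg.tissue_od) / math.sqrt(3.0)
    )
    i0 = np.asarray(cfg.background, dtype=np.float64)
    img = i0 * np.exp(-od)

    if cfg.noise_sd > 0:
        rng = _marker_rng(cfg, marker)
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SlideImage(pixels, marker=marker, mpp=cfg.mpp)


def _invert_displacement(
    gt: GroundTruth, round_index: int, width: int, height: int, stride: int = 4
) -> np.ndarray:
    """Reference coordinates r(u) solving r + T(r) = u on the full grid.

    T is the total (shift + field) displacement over reference coords.
    Solved by fixed-point iteration on a stride-subsampled grid (the
    field is smooth at the ~100 px scale) and bilinearly upsampled.
    Returns an array of shape (2, H, W) holding (ry, rx).
    """
    sx, sy = gt.per_round_shift[round_index]
    fld = gt.per_round_field[round_index]
    ys, xs = np.mgrid[0:height:stride, 0:width:stride].astype(np.float64)
    rx = xs - sx
    ry = ys - sy
    for _ in range(12):
        fx, fy = fld(rx, ry)
        rx_new = xs - sx - fx
        ry_new = ys - sy - fy
        if max(np.max(np.abs(rx_new - rx)), np.max(np.abs(ry_new - ry))) < 1e-3:
            rx, ry = rx_new, ry_new
            break
        rx, ry = rx_new, ry_new
    if stride == 1:
        return np.stack([ry, rx])
    # upsample the smooth inverse map to full resolution
    full = np.empty((2, height, width), dtype=np.float64)
    yy = np.arange(height) / stride
    xx = np.arange(width) / stride
    for k, comp in enumerate((ry, rx)):
        full[k] = ndimage.map_coordinates(
            comp, np.meshgrid(yy, xx, indexing="ij"), order=1, mode="nearest"
        )
    return full


def deform_round(
    image: SlideImage, gt: GroundTruth, round_index: int, order: int | None = None
) -> SlideImage:
    """Resample a rendered round under its stored rigid shift + field.

    Emulates the tissue shifts and micro-deformations the staining
    procedure introduces between rounds. Integer pure-shift cases are
    resampled exactly; out-of-frame regions fill with the background
    color.
    """
    if round_index not in gt.per_round_shift:
        raise KeyError(f"no stored deformation for round {round_index}")
    cfg = gt.config
    h, w = image.pixels.shape[:2]
    sx, sy = gt.per_round_shift[round_index]
    fld = gt.per_round_field[round_index]

    if fld.scale == 0.0 or len(fld.sigmas) == 0:
        coords = np.mgrid[0:h, 0:w].astype(np.float64)
        coords[0] -= sy
        coords[1] -= sx
    else:
        coords = _invert_displacement(gt, round_index, w, h)
    if order is None:
        exact = fld.scale == 0.0 and sx == int(sx) and sy == int(sy)
        order = 0 if exact else 1
    out = np.empty_like(image.pixels)
    for c in range(3):
        out[..., c] = np.clip(
            np.rint(
                ndimage.map_coordinates(
                    image.pixels[..., c].astype(np.float64),
                    coords,
                    order=order,
                    mode="constant",
                    cval=float(cfg.background[c]),
                )
            ),
            0,
            255,
        ).astype(np.uint8)
    return SlideImage(out, marker=image.marker, mpp=image.mpp)


def true_label_image(gt: GroundTruth, config: SimConfig | None = None) -> np.ndarray:
    """Rasterize the ground-truth nuclei as a label image (pixel
    coverage > 0.5 labeled by cell id) — the oracle counterpart of the
    segmentation module's output."""
    cfg = config or gt.config
    labels = np.zeros((cfg.height, cfg.width), dtype=np.int32)
    if len(gt.cells) == 0:
        return labels
    _, per_cell = _ellipse_coverage(cfg, gt.cells)
    ids = gt.cells["id"].to_numpy()
    for i in range(len(gt.cells)):
        x0, y0, c = per_cell[i]
        if c.size == 0:
            continue
        h, w = c.shape
        region = labels[y0 : y0 + h, x0 : x0 + w]
        region[c > 0.5] = ids[i]
    return labels


# ---------------------------------------------------------------------------
# artifacts

_ARTIFACT_KINDS = {"fold", "blur", "non_tissue"}


def add_artifacts(
    image: SlideImage, spec: Sequence[dict]
) -> tuple[SlideImage, dict[str, np.ndarray]]:
    """Paint artifacts onto a rendered round and return truth masks.

    Supported kinds:

    - ``fold``: darkened axis-aligned band — ``{"kind": "fold", "x0":
      int, "width": int, "orientation": "vertical"|"horizontal",
      "factor": float}``
    - ``blur``: locally low-pass-filtered disc — ``{"kind": "blur",
      "cx": int, "cy": int, "radius": int, "sigma": float}``
    - ``non_tissue``: margin strip repainted a distinct color —
      ``{"kind": "non_tissue", "side": "left"|"right"|"top"|"bottom",
      "margin": int, "color": (r, g, b)}``

    The returned masks mark exactly the modified pixels.
    """
    h, w = image.pixels.shape[:2]
    out = image.pixels.astype(np.float64)
    masks: dict[str, np.ndarray] = {}
    for item in spec:
        kind = item.get("kind")
        if kind not in _ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}")
        mask = np.zeros((h, w), dtype=bool)
        if kind == "fold":
            x0 = int(item["x0"])
            width = int(item["width"])
            factor = float(item.get("factor", 0.35))
            if item.get("orientation", "vertical") == "vertical":
                mask[:, x0 : x0 + width] = True
            else:
                mask[x0 : x0 + width, :] = True
            out[mask] *= factor
        elif kind == "blur":
            cx, cy = int(item["cx"]), int(item["cy"])
            radius = int(item["radius"])
            sigma = float(item.get("sigma", 6.0))
            ys, xs = np.mgrid[0:h, 0:w]
            mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius * radius
            blurred = np.stack(
                [ndimage.gaussian_filter(out[..., c], sigma) for c in range(3)], axis=-1
            )
            out[mask] = blurred[mask]
        elif kind == "non_tissue":
            margin = int(item["margin"])
            side = item.get("side", "left")
            color = np.asarray(item.get("color", (233, 200, 208)), dtype=np.float64)
            if side == "left":
                mask[:, :margin] = True
            elif side == "right":
                mask[:, w - margin :] = True
            elif side == "top":
                mask[:margin, :] = True
            elif side == "bottom":
                mask[h - margin :, :] = True
            else:
                raise ValueError(f"unknown side {side!r}")
            out[mask] = color
        masks[kind] = masks.get(kind, np.zeros((h, w), bool)) | mask
    pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return SlideImage(pixels, marker=image.marker, mpp=image.mpp), masks
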