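"""Round-to-reference registration.

Each marker round is aligned to the hematoxylin reference in four
steps: (1) a global rigid (translation) alignment found by normalized
cross-correlation at downsampled resolution and refined at full
resolution; (2) chunkwise NCC template matching that yields at most one
correspondence-point candidate per chunk of a grid over the reference;
(3) pruning of candidates whose displacement deviates from the local
(m-nearest-neighbor) componentwise median by more than a tolerance;
(4) natural-neighbor (Sibson) interpolation of the accepted residual
displacements into a dense distortion field used to warp the moving
round into the reference frame.

Sign convention: a displacement ``(dx, dy)`` maps reference coordinates
into the moving frame — tissue at reference position ``(x, y)`` is
found at ``(x + dx, y + dy)`` in the moving image, and warping samples
the moving image at exactly those coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, QhullError, cKDTree
from skimage.feature import match_template
from skimage.transform import downscale_local_mean

from scihc.image import SlideImage, as_gray
from scihc.tiling import TileGrid, build_tile_grid


@dataclass(frozen=True)
class RigidShift:
    """Global translation (reference -> moving) with its NCC peak score."""

    dx: float
    dy: float
    score: float


@dataclass
class CorrPoint:
    """One chunk's correspondence candidate.

    ``x, y`` anchor the measurement at the reference chunk center;
    ``dx, dy`` is the residual displacement after rigid alignment.
    """

    x: float
    y: float
    dx: float
    dy: float
    score: float
    accepted: bool = True


@dataclass
class RegistrationParams:
    downsample: int = 16
    chunk_size: int = 256        # correspondence-grid spacing
    template_size: int = 128
    search_radius: int = 64
    min_score: float = 0.5
    min_variance: float | None = None   # default: 1e-4 * intensity_range^2
    neighbors_m: int = 8
    tolerance: float = 10.0
    raster_step: int = 16        # discrete field-evaluation stride


def _subpixel_peak(resp: np.ndarray, iy: int, ix: int) -> tuple[float, float]:
    """Quadratic (parabolic) refinement of an NCC peak, one axis at a time."""

    def refine(vm, v0, vp):
        denom = vm - 2.0 * v0 + vp
        if denom >= 0 or abs(denom) < 1e-12:
            return 0.0
        off = 0.5 * (vm - vp) / denom
        return float(np.clip(off, -0.5, 0.5))

    oy = ox = 0.0
    if 0 < iy < resp.shape[0] - 1:
        oy = refine(resp[iy - 1, ix], resp[iy, ix], resp[iy + 1, ix])
    if 0 < ix < resp.shape[1] - 1:
        ox = refine(resp[iy, ix - 1], resp[iy, ix], resp[iy, ix + 1])
    return oy, ox


def _match(window: np.ndarray, template: np.ndarray):
    """NCC of a template within a search window; returns (score, py, px)
    where (py, px) is the subpixel top-left position of the best match."""
    resp = match_template(window, template)
    iy, ix = np.unravel_index(int(np.argmax(resp)), resp.shape)
    oy, ox = _subpixel_peak(resp, iy, ix)
    return float(resp[iy, ix]), iy + oy, ix + ox


def rigid_align(
    reference: SlideImage | np.ndarray,
    moving: SlideImage | np.ndarray,
    downsample: int = 16,
) -> RigidShift:
    """Global translation maximizing NCC, coarse-to-fine.

    The search runs at ``1/downsample`` resolution over the full frame
    (a central crop of the moving image is the template) and is then
    refined at full resolution within ``+-downsample`` px.
    """
    ref = as_gray(reference)
    mov = as_gray(moving)
    if ref.std() == 0 or mov.std() == 0:
        raise ValueError("rigid_align requires non-constant images")

    ref_ds = downscale_local_mean(ref, (downsample, downsample))
    mov_ds = downscale_local_mean(mov, (downsample, downsample))

    # template: central half of the downsampled moving image
    th, tw = max(mov_ds.shape[0] // 2, 4), max(mov_ds.shape[1] // 2, 4)
    ty = (mov_ds.shape[0] - th) // 2
    tx = (mov_ds.shape[1] - tw) // 2
    _, py, px = _match(ref_ds, mov_ds[ty : ty + th, tx : tx + tw])
    dx0 = (tx - px) * downsample
    dy0 = (ty - py) * downsample

    # full-resolution refinement within +-downsample px
    th = min(512, ref.shape[0] // 2)
    tw = min(512, ref.shape[1] // 2)
    cy, cx = ref.shape[0] // 2, ref.shape[1] // 2
    ty = cy - th // 2
    tx = cx - tw // 2
    pad = downsample + 2
    wy0 = int(round(ty + dy0)) - pad
    wx0 = int(round(tx + dx0)) - pad
    wy1 = wy0 + th + 2 * pad
    wx1 = wx0 + tw + 2 * pad
    wy0c, wx0c = max(wy0, 0), max(wx0, 0)
    window = mov[wy0c : max(wy1, 0), wx0c : max(wx1, 0)]
    template = ref[ty : ty + th, tx : tx + tw]
    if window.shape[0] <= th or window.shape[1] <= tw or template.std() == 0:
        return RigidShift(float(dx0), float(dy0), score=0.0)
    score, qy, qx = _match(window, template)
    # template content at reference (ty, tx) sits at (wy0c + qy, wx0c + qx)
    return RigidShift(
        dx=float(wx0c + qx - tx), dy=float(wy0c + qy - ty), score=score
    )


def shift_image(gray: np.ndarray, shift: RigidShift, cval: float = 0.0) -> np.ndarray:
    """Resample ``gray`` at ``(x + dx, y + dy)``: rigid-aligns a moving
    image into the reference frame."""
    coords = np.mgrid[0 : gray.shape[0], 0 : gray.shape[1]].astype(np.float64)
    coords[0] += shift.dy
    coords[1] += shift.dx
    return ndimage.map_coordinates(gray, coords, order=1, mode="constant", cval=cval)


def find_correspondences(
    reference: SlideImage | np.ndarray,
    moving: SlideImage | np.ndarray,
    grid: TileGrid | None = None,
    template_size: int = 128,
    search_radius: int = 64,
    min_score: float = 0.5,
    min_variance: float | None = None,
) -> list[CorrPoint]:
    """Chunkwise NCC correspondence candidates (moving already
    rigid-aligned to the reference frame).

    For each chunk of ``grid`` a ``template_size`` square template
    centered on the chunk is cut from the *reference* and searched in
    the moving image within ``search_radius`` px, so the measured
    residual displacement is anchored exactly at the reference chunk
    center. Chunks whose template variance falls below ``min_variance``
    (default ``1e-4 * intensity_range**2``: featureless background) or
    whose NCC peak falls below ``min_score`` yield no candidate.
    """
    ref = as_gray(reference)
    mov = as_gray(moving)
    if grid is None:
        grid = build_tile_grid(ref.shape[1], ref.shape[0], 256)
    if template_size >= grid.tile_size + search_radius:
        raise ValueError("template_size too large for the chunk grid")
    if search_radius <= 0:
        raise ValueError("search_radius must be > 0")
    rng_span = float(ref.max() - ref.min())
    if min_variance is None:
        min_variance = 1e-4 * rng_span * rng_span

    half = template_size // 2
    points: list[CorrPoint] = []
    for row, col, _ in grid.iter_tiles():
        cx, cy = grid.tile_center(row, col)
        tx = int(round(cx)) - half
        ty = int(round(cy)) - half
        if tx < 0 or ty < 0 or tx + template_size > ref.shape[1] or ty + template_size > ref.shape[0]:
            continue
        template = ref[ty : ty + template_size, tx : tx + template_size]
        if template.var() < min_variance:
            continue
        wy0 = max(ty - search_radius, 0)
        wx0 = max(tx - search_radius, 0)
        window = mov[
            wy0 : ty + template_size + search_radius,
            wx0 : tx + template_size + search_radius,
        ]
        if window.shape[0] < template_size or window.shape[1] < template_size:
            continue
        if window.std() == 0:
            continue
        score, qy, qx = _match(window, template)
        if score < min_score:
            continue
        points.append(
            CorrPoint(
                x=float(cx),
                y=float(cy),
                dx=float(wx0 + qx - tx),
                dy=float(wy0 + qy - ty),
                score=score,
            )
        )
    return points


def prune_correspondences(
    points: Sequence[CorrPoint], neighbors_m: int = 8, tolerance: float = 10.0
) -> list[CorrPoint]:
    """Remove locally inconsistent candidates.

    A point is rejected when the Euclidean norm of its displacement
    minus the componentwise median displacement of its ``neighbors_m``
    nearest surviving candidates exceeds ``tolerance``; points with
    fewer than ``neighbors_m`` neighbors are kept. The single-pass rule
    is iterated to a fixed point so the operation is idempotent.
    """
    if neighbors_m < 1:
        raise ValueError("neighbors_m must be >= 1")
    kept = list(points)
    while True:
        n = len(kept)
        if n <= neighbors_m:  # every point has fewer than m neighbors
            return kept
        xy = np.array([[p.x, p.y] for p in kept])
        d = np.array([[p.dx, p.dy] for p in kept])
        tree = cKDTree(xy)
        _, idx = tree.query(xy, k=neighbors_m + 1)
        keep_mask = np.ones(n, dtype=bool)
        for i in range(n):
            nbrs = [j for j in idx[i] if j != i][:neighbors_m]
            med = np.median(d[nbrs], axis=0)
            if float(np.hypot(*(d[i] - med))) > tolerance:
                keep_mask[i] = False
        if keep_mask.all():
            return kept
        kept = [p for p, k in zip(kept, keep_mask) if k]


# ---------------------------------------------------------------------------
# natural-neighbor distortion field


def _clip_halfplane(poly: np.ndarray, a: np.ndarray, b: float) -> np.ndarray:
    """Clip a convex polygon (n, 2) to the halfplane a.p <= b
    (Sutherland-Hodgman)."""
    if len(poly) == 0:
        return poly
    vals = poly @ a - b
    out: list[np.ndarray] = []
    n = len(poly)
    for i in range(n):
        p, q = poly[i], poly[(i + 1) % n]
        vp, vq = vals[i], vals[(i + 1) % n]
        if vp <= 0:
            out.append(p)
        if (vp < 0 < vq) or (vq < 0 < vp):
            t = vp / (vp - vq)
            out.append(p + t * (q - p))
    return np.asarray(out) if out else np.zeros((0, 2))


def _bisector(s: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, float]:
    """Halfplane {p : |p - s| <= |p - t|} as (a, b) with a.p <= b."""
    a = t - s
    b = float(a @ (s + t)) / 2.0
    return a, b


def _polygon_area(poly: np.ndarray) -> float:
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


class DistortionField:
    """Natural-neighbor interpolant of accepted correspondence
    displacements, defined at every reference coordinate.

    Inside the convex hull of the support points the displacement is
    the Sibson (Voronoi-overlap) weighted average of the supports —
    exact at each support and continuous everywhere; outside the hull
    the nearest support's displacement is used. Exact Sibson weights
    are computed by convex-polygon clipping; a rasterized evaluation
    grid (``raster_step`` px, bilinear lookup) provides the fast path
    for dense warping.
    """

    def __init__(self, points: Sequence[CorrPoint], width: int, height: int):
        pts = [p for p in points if p.accepted]
        if not pts:
            raise ValueError("need at least one accepted correspondence point")
        self.support_xy = np.array([[p.x, p.y] for p in pts], dtype=np.float64)
        self.support_d = np.array([[p.dx, p.dy] for p in pts], dtype=np.float64)
        self.width = int(width)
        self.height = int(height)
        self._tree = cKDTree(self.support_xy)
        self._raster: np.ndarray | None = None
        self._raster_step: int | None = None

        self._tri = None
        if len(pts) >= 3:
            try:
                self._tri = Delaunay(self.support_xy)
            except QhullError:
                self._tri = None  # collinear supports
        if self._tri is not None:
            self._prepare_geometry()

    # -- exact Sibson machinery ------------------------------------------

    def _prepare_geometry(self) -> None:
        tri = self._tri
        pts = self.support_xy
        simp = tri.simplices
        a, b, c = pts[simp[:, 0]], pts[simp[:, 1]], pts[simp[:, 2]]
        # circumcenters
        d = 2.0 * (
            a[:, 0] * (b[:, 1] - c[:, 1])
            + b[:, 0] * (c[:, 1] - a[:, 1])
            + c[:, 0] * (a[:, 1] - b[:, 1])
        )
        ux = (
            (a**2).sum(1) * (b[:, 1] - c[:, 1])
            + (b**2).sum(1) * (c[:, 1] - a[:, 1])
            + (c**2).sum(1) * (a[:, 1] - b[:, 1])
        ) / d
        uy = (
            (a**2).sum(1) * (c[:, 0] - b[:, 0])
            + (b**2).sum(1) * (a[:, 0] - c[:, 0])
            + (c**2).sum(1) * (b[:, 0] - a[:, 0])
        ) / d
        self._cc = np.column_stack([ux, uy])
        self._cr2 = ((self._cc - a) ** 2).sum(1)

        # Delaunay neighbor sets and a generous clipping box
        nbrs: list[set[int]] = [set() for _ in pts]
        for s in simp:
            for i in range(3):
                for j in range(3):
                    if i != j:
                        nbrs[s[i]].add(s[j])
        self._neighbors = [np.array(sorted(s)) for s in nbrs]

    def _sibson_at(self, q: np.ndarray) -> np.ndarray:
        """Exact natural-neighbor displacement at one interior point."""
        pts = self.support_xy
        # exact hit on a support
        dist, nearest = self._tree.query(q)
        if dist < 1e-9:
            return self.support_d[nearest].copy()
        inside = (self._cr2 - ((self._cc - q) ** 2).sum(1)) > -1e-9
        cand = np.unique(self._tri.simplices[inside].ravel())
        if len(cand) == 0:  # numerical corner case: fall back to nearest
            return self.support_d[nearest].copy()
        # start from a box covering the conflicting circumdisks and grow
        # it until the clipped cell no longer touches the box: near-hull
        # queries own Voronoi cells far larger than any fixed bound
        reach = float(
            np.max(np.hypot(*(self._cc[inside] - q).T) + np.sqrt(self._cr2[inside]))
        ) + 1.0
        unit_box = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], float)
        for _ in range(60):
            cell_q = q + reach * unit_box
            for j in cand:
                a_, b_ = _bisector(q, pts[j])
                cell_q = _clip_halfplane(cell_q, a_, b_)
            if len(cell_q) == 0 or np.abs(cell_q - q).max() < reach * (1 - 1e-9):
                break
            reach *= 4.0
        w = np.zeros(len(cand))
        for k, j in enumerate(cand):
            piece = cell_q
            for v in self._neighbors[j]:
                a_, b_ = _bisector(pts[j], pts[v])
                piece = _clip_halfplane(piece, a_, b_)
            w[k] = _polygon_area(piece)
        tot = w.sum()
        if tot <= 0:
            return self.support_d[nearest].copy()
        return (w[:, None] * self.support_d[cand]).sum(0) / tot

    def _collinear_eval(self, xy: np.ndarray) -> np.ndarray:
        """<3 supports or collinear: 1-D linear interpolation along the
        principal axis, clamped at the ends (continuous everywhere)."""
        pts = self.support_xy
        if len(pts) == 1:
            return np.tile(self.support_d[0], (len(xy), 1))
        center = pts.mean(0)
        u, s, vt = np.linalg.svd(pts - center)
        axis = vt[0]
        t_sup = (pts - center) @ axis
        order = np.argsort(t_sup)
        t_sorted = t_sup[order]
        d_sorted = self.support_d[order]
        t_q = (xy - center) @ axis
        out = np.empty((len(xy), 2))
        for k in range(2):
            out[:, k] = np.interp(t_q, t_sorted, d_sorted[:, k])
        return out

    def evaluate(self, x, y, exact: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Displacement (dx, dy) at reference coordinates.

        ``exact=True`` computes Sibson weights analytically per query;
        ``exact=False`` uses the rasterized grid (bilinear), which is
        what dense warping uses.
        """
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        shape = np.broadcast(x, y).shape
        x, y = np.broadcast_arrays(x, y)
        xy = np.column_stack([np.ravel(x), np.ravel(y)])
        if not exact:
            rast, step = self._get_raster()
            coords = np.vstack([np.ravel(y) / step, np.ravel(x) / step])
            dx = ndimage.map_coordinates(rast[0], coords, order=1, mode="nearest")
            dy = ndimage.map_coordinates(rast[1], coords, order=1, mode="nearest")
            return dx.reshape(shape), dy.reshape(shape)

        if self._tri is None:
            out = self._collinear_eval(xy)
        else:
            out = np.empty((len(xy), 2))
            simplex = self._tri.find_simplex(xy)
            outside = simplex < 0
            if outside.any():
                _, nearest = self._tree.query(xy[outside])
                out[outside] = self.support_d[nearest]
            for i in np.flatnonzero(~outside):
                out[i] = self._sibson_at(xy[i])
        return out[:, 0].reshape(shape), out[:, 1].reshape(shape)

    def __call__(self, x, y):
        return self.evaluate(x, y, exact=True)

    def _get_raster(self, step: int = 16) -> tuple[np.ndarray, int]:
        if self._raster is None or self._raster_step != step:
            gx = np.arange(0, self.width + step, step, dtype=np.float64)
            gy = np.arange(0, self.height + step, step, dtype=np.float64)
            xs, ys = np.meshgrid(gx, gy)
            dx, dy = self.evaluate(xs, ys, exact=True)
            self._raster = np.stack([dx, dy])
            self._raster_step = step
        return self._raster, self._raster_step

    def dense(self, width: int | None = None, height: int | None = None) -> np.ndarray:
        """(2, H, W) displacement raster (dx, dy) over the full frame."""
        w = width or self.width
        h = height or self.height
        rast, step = self._get_raster()
        ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
        dx = ndimage.map_coordinates(rast[0], [ys / step, xs / step], order=1, mode="nearest")
        dy = ndimage.map_coordinates(rast[1], [ys / step, xs / step], order=1, mode="nearest")
        return np.stack([dx, dy])

    def to_dict(self) -> dict:
        return {
            "support_points": [
                {"x": float(x), "y": float(y), "dx": float(dx), "dy": float(dy)}
                for (x, y), (dx, dy) in zip(self.support_xy, self.support_d)
            ],
            "width": self.width,
            "height": self.height,
        }


def fit_distortion_field(
    points: Sequence[CorrPoint], width: int, height: int
) -> DistortionField:
    """Fit the natural-neighbor distortion field to accepted points.

    Raises ``ValueError`` when no accepted point remains (callers may
    fall back to rigid-only alignment).
    """
    return DistortionField(points, width=width, height=height)


def warp_to_reference(
    moving: SlideImage | np.ndarray,
    rigid: RigidShift,
    field: DistortionField | None = None,
) -> np.ndarray:
    """Resample the moving image into the reference frame.

    ``out(x, y) = moving(x + rigid.dx + field.dx(x, y),
    y + rigid.dy + field.dy(x, y))`` with bilinear interpolation.
    Out-of-bounds samples become NaN (the sentinel downstream intensity
    means exclude); the result is float64, shape (H, W) or (H, W, 3).
    """
    arr = moving.pixels if isinstance(moving, SlideImage) else np.asarray(moving)
    arr = arr.astype(np.float64)
    h, w = arr.shape[:2]
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    if field is not None:
        fdx, fdy = field.evaluate(xs, ys, exact=False)
    else:
        fdx = fdy = 0.0
    sx = xs + rigid.dx + fdx
    sy = ys + rigid.dy + fdy
    oob = (sx < 0) | (sx > w - 1) | (sy < 0) | (sy > h - 1)
    coords = np.vstack([sy.ravel(), sx.ravel()])
    if arr.ndim == 2:
        out = ndimage.map_coordinates(arr, coords, order=1, mode="nearest").reshape(h, w)
        out[oob] = np.nan
        return out
    out = np.empty_like(arr)
    for c in range(arr.shape[2]):
        out[..., c] = ndimage.map_coordinates(
            arr[..., c], coords, order=1, mode="nearest"
        ).reshape(h, w)
    out[oob] = np.nan
    return out


@dataclass
class RoundRegistration:
    """Result of registering one marker round to the reference."""

    rigid: RigidShift
    field: DistortionField | None
    points: list[CorrPoint]
    n_candidates: int

    def total_displacement(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Fitted rigid + non-rigid displacement at reference coords."""
        if self.field is None:
            return (
                np.broadcast_to(self.rigid.dx, np.shape(x)).astype(float),
                np.broadcast_to(self.rigid.dy, np.shape(y)).astype(float),
            )
        fdx, fdy = self.field.evaluate(x, y, exact=True)
        return self.rigid.dx + fdx, self.rigid.dy + fdy


def register_round(
    reference: SlideImage | np.ndarray,
    moving: SlideImage | np.ndarray,
    params: RegistrationParams | None = None,
) -> RoundRegistration:
    """Full registration of one round: rigid + pruned NCC
    correspondences + natural-neighbor field."""
    params = params or RegistrationParams()
    ref = as_gray(reference)
    mov = as_gray(moving)
    rigid = rigid_align(ref, mov, downsample=params.downsample)
    aligned = shift_image(mov, rigid, cval=float(np.median(mov)))
    grid = build_tile_grid(ref.shape[1], ref.shape[0], params.chunk_size)
    cands = find_correspondences(
        ref,
        aligned,
        grid,
        template_size=params.template_size,
        search_radius=params.search_radius,
        min_score=params.min_score,
        min_variance=params.min_variance,
    )
    points = prune_correspondences(cands, params.neighbors_m, params.tolerance)
    field = None
    if points:
        field = fit_distortion_field(points, ref.shape[1], ref.shape[0])
    return RoundRegistration(
        rigid=rigid, field=field, points=points, n_candidates=len(cands)
    )
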