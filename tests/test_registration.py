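import numpy as np
import pytest
from scipy import ndimage

from scihc import (
    CorrPoint,
    find_correspondences,
    fit_distortion_field,
    prune_correspondences,
    rigid_align,
    warp_to_reference,
)
from scihc.registration import RigidShift, register_round
from scihc.tiling import build_tile_grid
from scihc import SimConfig, deform_round, generate_ground_truth, render_round
from scihc.synthetic import HEMATOXYLIN


def _texture(shape, seed=0, sigma=3.0):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.normal(size=shape), sigma) * 50 + 128


# -- rigid alignment --------------------------------------------------------


def test_rigid_identical_images_is_zero():
    img = _texture((512, 512))
    s = rigid_align(img, img, downsample=8)
    assert abs(s.dx) <= 0.5 and abs(s.dy) <= 0.5
    assert s.score > 0.99


def test_rigid_recovers_known_translation():
    # content shifted by (dx, dy) = (+7, -3): moving(u) = ref(u - s)
    ref = _texture((512, 512), seed=3)
    mov = ndimage.shift(ref, (-3, 7), order=1, mode="nearest")
    s = rigid_align(ref, mov, downsample=8)
    assert abs(s.dx - 7) <= 1.0 and abs(s.dy - (-3)) <= 1.0


def test_rigid_constant_image_raises():
    with pytest.raises(ValueError):
        rigid_align(np.full((256, 256), 5.0), _texture((256, 256)))


def test_ncc_invariant_to_affine_intensity_rescale():
    ref = _texture((512, 512), seed=4)
    mov = ndimage.shift(ref, (-5, 9), order=1, mode="nearest")
    s1 = rigid_align(ref, mov, downsample=8)
    s2 = rigid_align(ref, 3.0 * mov + 40.0, downsample=8)
    assert abs(s1.dx - s2.dx) <= 0.5 and abs(s1.dy - s2.dy) <= 0.5
    assert abs(s1.score - s2.score) < 0.02


# -- correspondences --------------------------------------------------------


def test_correspondences_recover_planted_residual():
    ref = _texture((768, 768), seed=5)
    mov = ndimage.shift(ref, (0, 4), order=1, mode="nearest")  # residual (4, 0)
    grid = build_tile_grid(768, 768, 256)
    pts = find_correspondences(ref, mov, grid, template_size=128, search_radius=32)
    assert len(pts) >= 4
    for p in pts:
        assert abs(p.dx - 4) <= 1.0 and abs(p.dy) <= 1.0
        assert -1.0 - 1e-9 <= p.score <= 1.0 + 1e-9


def test_textureless_chunk_yields_no_candidate():
    ref = _texture((512, 512), seed=6)
    ref[:256, :256] = 100.0  # flat quadrant
    grid = build_tile_grid(512, 512, 256)
    pts = find_correspondences(ref, ref.copy(), grid, template_size=128,
                               search_radius=32)
    centers = {(round(p.x), round(p.y)) for p in pts}
    assert (127, 127) not in centers  # flat chunk gated out
    assert len(pts) == 3


# -- pruning ----------------------------------------------------------------


def _grid_points(disp, n=3, spacing=100.0):
    pts = []
    for i in range(n):
        for j in range(n):
            pts.append(CorrPoint(x=j * spacing, y=i * spacing,
                                 dx=disp[0], dy=disp[1], score=0.9))
    return pts


def test_prune_removes_single_outlier():
    pts = _grid_points((4.0, 0.0))
    pts[4] = CorrPoint(x=pts[4].x, y=pts[4].y, dx=40.0, dy=30.0, score=0.9)
    kept = prune_correspondences(pts, neighbors_m=8, tolerance=10.0)
    assert len(kept) == 8
    assert all((p.dx, p.dy) == (4.0, 0.0) for p in kept)


def test_prune_keeps_consistent_set():
    pts = _grid_points((2.0, -1.0))
    assert len(prune_correspondences(pts, 8, 10.0)) == len(pts)


def test_prune_keeps_points_with_few_neighbors():
    one = [CorrPoint(0, 0, 50.0, 50.0, 0.9)]
    assert prune_correspondences(one, 8, 1.0) == one


def test_prune_is_idempotent(rng):
    pts = [
        CorrPoint(x=float(x), y=float(y),
                  dx=float(rng.normal(3, 2)), dy=float(rng.normal(0, 2)), score=0.8)
        for x, y in rng.uniform(0, 1000, size=(60, 2))
    ]
    once = prune_correspondences(pts, 8, 4.0)
    twice = prune_correspondences(once, 8, 4.0)
    assert once == twice


# -- distortion field -------------------------------------------------------


def test_field_exact_at_supports(rng):
    pts = [
        CorrPoint(x=float(x), y=float(y),
                  dx=float(rng.normal(0, 5)), dy=float(rng.normal(0, 5)), score=0.9)
        for x, y in rng.uniform(50, 450, size=(15, 2))
    ]
    field = fit_distortion_field(pts, 512, 512)
    for p in pts:
        dx, dy = field.evaluate(p.x, p.y)
        assert abs(float(dx) - p.dx) < 1e-6
        assert abs(float(dy) - p.dy) < 1e-6


def test_field_constant_data_everywhere(rng):
    pts = [CorrPoint(x=float(x), y=float(y), dx=2.0, dy=5.0, score=0.9)
           for x, y in rng.uniform(0, 500, size=(12, 2))]
    field = fit_distortion_field(pts, 512, 512)
    xs = rng.uniform(0, 500, size=50)
    ys = rng.uniform(0, 500, size=50)
    dx, dy = field.evaluate(xs, ys)
    np.testing.assert_allclose(dx, 2.0, atol=1e-9)
    np.testing.assert_allclose(dy, 5.0, atol=1e-9)


def test_field_zero_points_raises():
    with pytest.raises(ValueError):
        fit_distortion_field([], 100, 100)


def _sibson_weights_bruteforce(supports, q, step=0.25, pad=150.0):
    """Rasterized-Voronoi Sibson oracle: weight of support i = count of
    raster nodes stolen from i's Voronoi cell by inserting q."""
    lo = supports.min(0) - pad
    hi = supports.max(0) + pad
    xs = np.arange(lo[0], hi[0], step)
    ys = np.arange(lo[1], hi[1], step)
    gx, gy = np.meshgrid(xs, ys)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    d_sup = ((nodes[:, None, :] - supports[None, :, :]) ** 2).sum(-1)
    site = d_sup.argmin(1)
    d_site = d_sup[np.arange(len(nodes)), site]
    d_q = ((nodes - q) ** 2).sum(-1)
    stolen = d_q < d_site
    w = np.bincount(site[stolen], minlength=len(supports)).astype(float)
    return w / w.sum()


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_field_matches_bruteforce_sibson_oracle(seed):
    # registration-like geometry: jittered grid of supports, interior
    # queries (hull-adjacent slivers make the rasterized oracle itself
    # ill-conditioned, so both sides stay away from the hull edge)
    rng = np.random.default_rng(seed)
    gx, gy = np.meshgrid([10.0, 50.0, 90.0], [10.0, 50.0, 90.0])
    supports = np.column_stack([gx.ravel(), gy.ravel()]) + rng.uniform(-8, 8, (9, 2))
    disp = rng.normal(0, 5, size=(9, 2))
    pts = [CorrPoint(x=s[0], y=s[1], dx=d[0], dy=d[1], score=0.9)
           for s, d in zip(supports, disp)]
    field = fit_distortion_field(pts, 100, 100)
    for q in rng.uniform(30, 70, size=(4, 2)):
        w = _sibson_weights_bruteforce(supports, q)
        expect = w @ disp
        dx, dy = field.evaluate(q[0], q[1])
        assert abs(float(dx) - expect[0]) < 0.05
        assert abs(float(dy) - expect[1]) < 0.05


def test_field_unit_square_interpolation_monotone():
    # corners with displacement (0,0) on the left, (10,0) on the right:
    # values stay in [0,10] x {0} and increase along x
    pts = [
        CorrPoint(0, 0, 0.0, 0.0, 1.0),
        CorrPoint(0, 100, 0.0, 0.0, 1.0),
        CorrPoint(100, 0, 10.0, 0.0, 1.0),
        CorrPoint(100, 100, 10.0, 0.0, 1.0),
    ]
    field = fit_distortion_field(pts, 100, 100)
    xs = np.linspace(5, 95, 19)
    dx, dy = field.evaluate(xs, np.full_like(xs, 50.0))
    assert (dx >= -1e-9).all() and (dx <= 10 + 1e-9).all()
    np.testing.assert_allclose(dy, 0.0, atol=1e-9)
    assert (np.diff(dx) >= -1e-6).all()


# -- warping ----------------------------------------------------------------


def test_warp_identity():
    img = _texture((256, 256), seed=8)
    out = warp_to_reference(img, RigidShift(0.0, 0.0, 1.0), None)
    np.testing.assert_allclose(out, img, atol=1e-9)


def test_warp_fully_out_of_bounds_is_sentinel():
    img = _texture((64, 64))
    out = warp_to_reference(img, RigidShift(1000.0, 0.0, 1.0), None)
    assert np.isnan(out).all()


def test_warp_with_true_field_reduces_residual():
    cfg = SimConfig(width=512, height=512, n_cells=150, seed=15,
                    markers=("M",), max_shift=10.0, field_amplitude=6.0,
                    field_smoothness=150.0)
    gt = generate_ground_truth(cfg)
    ref = render_round(gt, "M")
    mov = deform_round(ref, gt, 0)
    sx, sy = gt.per_round_shift[0]
    fld = gt.per_round_field[0]
    ys, xs = np.mgrid[0:512, 0:512].astype(float)
    fdx, fdy = fld(xs, ys)
    coords = np.vstack([(ys + sy + fdy).ravel(), (xs + sx + fdx).ravel()])
    warped = ndimage.map_coordinates(
        mov.pixels[..., 1].astype(float), coords, order=1, mode="nearest"
    ).reshape(512, 512)
    ref_g = ref.pixels[..., 1].astype(float)
    inner = np.s_[50:-50, 50:-50]
    before = np.abs(mov.pixels[..., 1].astype(float) - ref_g)[inner].mean()
    after = np.abs(warped - ref_g)[inner].mean()
    assert after < before * 0.5


def test_end_to_end_recovery_small():
    cfg = SimConfig(width=1024, height=1024, n_cells=800, seed=3,
                    markers=("M",), max_shift=25.0, field_amplitude=12.0)
    gt = generate_ground_truth(cfg)
    ref = render_round(gt, HEMATOXYLIN)
    mov = deform_round(render_round(gt, "M"), gt, 0)
    reg = register_round(ref, mov)
    x = gt.cells.x.to_numpy()
    y = gt.cells.y.to_numpy()
    tdx, tdy = gt.true_displacement(0, x, y)
    fdx, fdy = reg.total_displacement(x, y)
    err = np.hypot(tdx - fdx, tdy - fdy)
    assert err.mean() <= 2.0
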