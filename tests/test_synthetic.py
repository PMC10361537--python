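"""Simulator ground-truth consistency: every planted quantity must be
re-measurable from the outputs by brute force."""

import math

import numpy as np
import pandas as pd
import pytest

from scihc import (
    SimConfig,
    add_artifacts,
    deform_round,
    generate_ground_truth,
    plant_contacts,
    render_round,
)
from scihc.synthetic import HEMATOXYLIN, true_label_image
from scihc.segmentation import StainModel, deconvolve_stains


def test_cell_count_and_bounds(mini_gt, mini_cfg):
    assert len(mini_gt.cells) == mini_cfg.n_cells
    assert (mini_gt.cells.x >= 0).all() and (mini_gt.cells.x < mini_cfg.width).all()
    assert (mini_gt.cells.y >= 0).all() and (mini_gt.cells.y < mini_cfg.height).all()
    for marker in mini_cfg.markers:
        assert set(mini_gt.cells[marker].unique()) <= {0, 1}


def test_same_seed_is_bit_identical(mini_cfg):
    a = generate_ground_truth(mini_cfg)
    b = generate_ground_truth(mini_cfg)
    pd.testing.assert_frame_equal(a.cells, b.cells)
    for r in range(len(mini_cfg.markers)):
        assert a.per_round_shift[r] == b.per_round_shift[r]
        assert a.per_round_field[r].to_dict() == b.per_round_field[r].to_dict()


def test_min_center_separation(mini_gt):
    xy = mini_gt.cells[["x", "y"]].to_numpy()
    major = mini_gt.cells["major_axis"].to_numpy()
    d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).transpose(2, 0, 1))
    np.fill_diagonal(d, np.inf)
    sep = np.maximum(major[:, None], major[None, :])
    assert (d >= sep - 1e-9).all()


def test_phenotype_frequency_binomial():
    # observed positive fraction within 3 binomial SDs of the planted rate
    cfg = SimConfig(width=2048, height=2048, n_cells=2000, seed=9,
                    markers=("M",), phenotype_frequencies={"M": 0.3})
    gt = generate_ground_truth(cfg)
    frac = gt.cells["M"].mean()
    sd = math.sqrt(0.3 * 0.7 / 2000)
    assert abs(frac - 0.3) <= 3 * sd


def test_impossible_packing_raises():
    cfg = SimConfig(width=128, height=128, n_cells=2000, seed=0)
    with pytest.raises(RuntimeError, match="place"):
        generate_ground_truth(cfg)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimConfig(mpp=0.0)
    with pytest.raises(ValueError):
        SimConfig(phenotype_frequencies={"CD138": 1.5})


# -- contact planting -------------------------------------------------------


def _contact_fraction_bruteforce(gt, qm, tm, radius_um):
    cells = gt.cells
    q = cells[cells[qm] == 1]
    t = cells[cells[tm] == 1]
    r_px = radius_um / gt.config.mpp
    hits = 0
    for _, row in q.iterrows():
        others = t[t.id != row.id]
        d = np.hypot(others.x - row.x, others.y - row.y)
        hits += bool((d <= r_px).any())
    return hits / len(q)


def test_plant_contacts_full_fraction():
    cfg = SimConfig(width=1024, height=1024, n_cells=300, seed=8,
                    markers=("Q", "T"),
                    phenotype_frequencies={"Q": 0.15, "T": 0.4})
    gt = plant_contacts(generate_ground_truth(cfg), "Q", "T", 1.0, 12.0)
    assert _contact_fraction_bruteforce(gt, "Q", "T", 12.0) == 1.0


def test_plant_contacts_zero_is_identity(mini_gt):
    gt = plant_contacts(mini_gt, "CD138", "BDCA2", 0.0, 10.0)
    pd.testing.assert_frame_equal(gt.cells, mini_gt.cells)


def test_plant_contacts_half_fraction():
    cfg = SimConfig(width=2048, height=2048, n_cells=2000, seed=5,
                    markers=("Q", "T"),
                    phenotype_frequencies={"Q": 0.1, "T": 0.12})
    gt = plant_contacts(generate_ground_truth(cfg), "Q", "T", 0.5, 10.0)
    frac = _contact_fraction_bruteforce(gt, "Q", "T", 10.0)
    assert 0.5 <= frac <= 1.0


def test_plant_contacts_moves_only_targets():
    cfg = SimConfig(width=1024, height=1024, n_cells=300, seed=4,
                    markers=("Q", "T"),
                    phenotype_frequencies={"Q": 0.15, "T": 0.35})
    gt0 = generate_ground_truth(cfg)
    gt1 = plant_contacts(gt0, "Q", "T", 0.8, 10.0)
    moved = (gt0.cells[["x", "y"]].to_numpy() != gt1.cells[["x", "y"]].to_numpy()).any(1)
    t_only = (gt0.cells["T"] == 1) & (gt0.cells["Q"] == 0)
    assert moved.sum() > 0
    assert (~moved | t_only.to_numpy()).all()


def test_plant_contacts_validates_inputs(mini_gt):
    with pytest.raises(ValueError):
        plant_contacts(mini_gt, "CD138", "BDCA2", 1.2, 10.0)
    with pytest.raises(ValueError):
        plant_contacts(mini_gt, "CD138", "BDCA2", 0.5, -1.0)
    with pytest.raises(KeyError):
        plant_contacts(mini_gt, "CD138", "nope", 0.5, 10.0)


# -- rendering --------------------------------------------------------------


def _aec_amount(image, cfg):
    model = StainModel(
        vectors={"hematoxylin": cfg.hematoxylin_rgb, "aec": cfg.aec_rgb},
        background=cfg.background,
    )
    return deconvolve_stains(image.pixels, model)["aec"]


def test_render_empty_scene_is_background():
    cfg = SimConfig(width=128, height=128, n_cells=0, noise_sd=2.0, seed=1,
                    tissue_od=0.0)
    gt = generate_ground_truth(cfg)
    img = render_round(gt, HEMATOXYLIN)
    for c in range(3):
        assert abs(img.pixels[..., c].mean() - cfg.background[c]) < 1.0


def test_positive_cell_carries_chromogen(mini_gt, mini_cfg):
    img = render_round(mini_gt, "CD138")
    labels = true_label_image(mini_gt)
    aec = _aec_amount(img, mini_cfg)
    pos = mini_gt.cells[mini_gt.cells.CD138 == 1].id.to_numpy()
    neg = mini_gt.cells[mini_gt.cells.CD138 == 0].id.to_numpy()
    mean_pos = aec[np.isin(labels, pos)].mean()
    mean_neg = aec[np.isin(labels, neg)].mean()
    assert mean_pos > mean_neg + 0.3


def test_hematoxylin_round_has_no_chromogen(mini_gt, mini_cfg):
    img = render_round(mini_gt, HEMATOXYLIN)
    aec = _aec_amount(img, mini_cfg)
    # crosstalk + noise only: compare against the background AEC level
    bg = aec[true_label_image(mini_gt) == 0]
    nuc = aec[true_label_image(mini_gt) > 0]
    assert nuc.mean() < bg.mean() + 3 * (bg.std() + 1e-9) + 0.1


def test_render_unknown_marker_raises(mini_gt):
    with pytest.raises(KeyError):
        render_round(mini_gt, "CD999")


# -- deformation ------------------------------------------------------------


def test_deform_identity_when_zero(mini_cfg):
    cfg = SimConfig(**{**mini_cfg.__dict__, "max_shift": 0.0, "field_amplitude": 0.0})
    gt = generate_ground_truth(cfg)
    img = render_round(gt, "CD138")
    out = deform_round(img, gt, 0)
    np.testing.assert_array_equal(out.pixels, img.pixels)


def test_deform_pure_integer_shift_translates_exactly(mini_gt, mini_cfg):
    import dataclasses
    gt = dataclasses.replace(mini_gt)
    gt.per_round_shift = {0: (7.0, -3.0)}
    from scihc.synthetic import BumpField
    gt.per_round_field = {0: BumpField.zero()}
    img = render_round(mini_gt, "CD138")
    out = deform_round(img, gt, 0)
    h, w = img.pixels.shape[:2]
    # content at reference (x, y) appears at (x + 7, y - 3)
    np.testing.assert_array_equal(
        out.pixels[20 : h - 20, 20 : w - 20],
        img.pixels[23 : h - 17, 13 : w - 27],
    )


def test_field_magnitude_bounded(mini_gt, mini_cfg):
    ys, xs = np.mgrid[0 : mini_cfg.height : 3, 0 : mini_cfg.width : 3]
    for r in range(len(mini_cfg.markers)):
        dx, dy = mini_gt.per_round_field[r](xs.astype(float), ys.astype(float))
        assert np.hypot(dx, dy).max() <= mini_cfg.field_amplitude + 1e-6
        sx, sy = mini_gt.per_round_shift[r]
        assert math.hypot(sx, sy) <= mini_cfg.max_shift + 1e-9


def test_deform_unknown_round_raises(mini_gt):
    img = render_round(mini_gt, "CD138")
    with pytest.raises(KeyError):
        deform_round(img, mini_gt, 99)


# -- artifacts --------------------------------------------------------------


def test_artifacts_empty_spec_identity(mini_ref):
    out, masks = add_artifacts(mini_ref, [])
    np.testing.assert_array_equal(out.pixels, mini_ref.pixels)
    assert masks == {}


def test_blur_disc_mask_area(mini_ref):
    r = 60
    _, masks = add_artifacts(mini_ref, [{"kind": "blur", "cx": 250, "cy": 250, "radius": r}])
    area = masks["blur"].sum()
    assert abs(area - math.pi * r * r) / (math.pi * r * r) < 0.02


def test_fold_band_mask_area(mini_ref):
    _, masks = add_artifacts(mini_ref, [{"kind": "fold", "x0": 100, "width": 40}])
    assert masks["fold"].sum() == 40 * mini_ref.height


def test_unknown_artifact_kind_raises(mini_ref):
    with pytest.raises(ValueError):
        add_artifacts(mini_ref, [{"kind": "scratch"}])


def test_masks_mark_exactly_modified_pixels(mini_ref):
    out, masks = add_artifacts(
        mini_ref, [{"kind": "non_tissue", "side": "left", "margin": 30}]
    )
    changed = (out.pixels != mini_ref.pixels).any(axis=2)
    assert (changed <= masks["non_tissue"]).all()
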