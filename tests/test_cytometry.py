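import numpy as np
import pandas as pd
import pytest

from scihc import GateSet, apply_gates, measure_marker, read_fcs, subset_coordinates, write_fcs
from scihc.cytometry import build_cell_table, export_cell_table
from scihc.fcs import sanitize_name


# -- measurement ------------------------------------------------------------


def _one_cell_labels(shape=(20, 20)):
    labels = np.zeros(shape, dtype=np.int32)
    labels[5:15, 5:15] = 1
    return labels


def test_constant_region_mean():
    labels = _one_cell_labels()
    meas = measure_marker(labels, np.full(labels.shape, 3.5))
    assert meas.loc[1, "mean_intensity"] == pytest.approx(3.5)
    assert not meas.loc[1, "excluded"]


def test_half_half_mean():
    labels = _one_cell_labels()
    sig = np.zeros(labels.shape)
    sig[:, 10:] = 1.0
    assert measure_marker(labels, sig).loc[1, "mean_intensity"] == pytest.approx(0.5)


def test_artifact_overlap_flags_exclusion():
    labels = _one_cell_labels()
    roi = np.ones(labels.shape, dtype=bool)
    roi[5:15, 5:8] = False  # 30% of the cell outside ROI
    meas = measure_marker(labels, np.ones(labels.shape), roi, max_artifact_overlap=0.25)
    assert meas.loc[1, "outside_fraction"] == pytest.approx(0.3)
    assert bool(meas.loc[1, "excluded"])


def test_nan_sentinel_excluded_from_mean():
    labels = _one_cell_labels()
    sig = np.full(labels.shape, 2.0)
    sig[5:15, 5:10] = np.nan
    meas = measure_marker(labels, sig, max_artifact_overlap=0.6)
    assert meas.loc[1, "mean_intensity"] == pytest.approx(2.0)
    assert meas.loc[1, "outside_fraction"] == pytest.approx(0.5)


def test_shape_mismatch_raises():
    with pytest.raises(ValueError):
        measure_marker(np.zeros((4, 4), int), np.zeros((5, 5)))


# -- gating -----------------------------------------------------------------


def _table(**markers):
    n = len(next(iter(markers.values())))
    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "x_um": np.linspace(0, 10, n),
            "y_um": np.zeros(n),
            "area_px": np.full(n, 50),
            "excluded": [False] * n,
            **markers,
        }
    )


def test_cdc1_cdc2_mutually_exclusive_gates():
    gates = GateSet.default_panel(t=0.5)
    table = _table(
        CD138=[0, 0, 0], BDCA2=[0, 0, 0], CD169=[0, 0, 0], CD68=[0, 0, 0],
        CD56=[0, 0, 0], CD66b=[0, 0, 0],
        CD141=[0.9, 0.9, 0.1], CD1c=[0.1, 0.9, 0.9],
    )
    smap = apply_gates(table, gates)
    assert list(smap.ids("cDC1")) == [1]       # CD141+ CD1c-
    assert list(smap.ids("cDC2")) == [3]       # CD141- CD1c+
    # double positive is neither cDC1 nor cDC2
    assert 2 not in set(smap.ids("cDC1")) | set(smap.ids("cDC2"))


def test_all_negative_cell_in_no_subset():
    gates = GateSet.default_panel(t=0.5)
    table = _table(**{m: [0.0] for m in
                      ("CD138", "BDCA2", "CD141", "CD1c", "CD169", "CD68", "CD56", "CD66b")})
    smap = apply_gates(table, gates)
    assert all(len(smap.ids(name)) == 0 for name in gates.subsets)


def test_excluded_cells_are_skipped():
    table = _table(CD138=[0.9, 0.9])
    table.loc[1, "excluded"] = True
    smap = apply_gates(table, GateSet({"plasmablast": "CD138 >= 0.5"}))
    assert list(smap.ids("plasmablast")) == [1]


def test_unknown_marker_in_gate_raises():
    table = _table(CD138=[0.9])
    with pytest.raises(KeyError):
        apply_gates(table, GateSet({"x": "CD999 >= 0.5"}))


def test_subset_coordinates_ordering_and_roundtrip(tmp_path):
    table = _table(CD138=[0.9, 0.1, 0.8, 0.7])
    smap = apply_gates(table, GateSet({"plasmablast": "CD138 >= 0.5"}))
    coords = subset_coordinates(smap, "plasmablast")
    assert list(coords["id"]) == sorted(coords["id"])
    p = tmp_path / "subset.csv"
    coords.to_csv(p, index=False)
    back = pd.read_csv(p)
    pd.testing.assert_frame_equal(back, coords, check_dtype=False)
    with pytest.raises(KeyError):
        subset_coordinates(smap, "nope")
    assert len(subset_coordinates(
        apply_gates(table, GateSet({"none": "CD138 >= 99"})), "none")) == 0


# -- FCS --------------------------------------------------------------------


def test_fcs_shape_contract(tmp_path):
    df = pd.DataFrame({"X_um": [1.0, 2.0, 3.0], "Y_um": [4.0, 5.0, 6.0],
                       "CD138": [0.1, 0.2, 0.3], "BDCA2": [0.0, 0.9, 0.5]})
    p = tmp_path / "cells.fcs"
    write_fcs(p, df)
    back = read_fcs(p)
    assert back.shape == (3, 4)


def test_fcs_roundtrip_single_precision(tmp_path, rng):
    df = pd.DataFrame(rng.uniform(0, 1e4, size=(500, 6)),
                      columns=["X_um", "Y_um", "a", "b", "c", "d"])
    p = tmp_path / "cells.fcs"
    write_fcs(p, df)
    back = read_fcs(p)
    rel = np.abs(back.to_numpy() - df.to_numpy()) / np.maximum(np.abs(df.to_numpy()), 1e-12)
    assert rel.max() <= 1e-5


def test_fcs_name_sanitization(tmp_path):
    df = pd.DataFrame({"CD66b (granulo)": [1.0, 2.0]})
    p = tmp_path / "cells.fcs"
    write_fcs(p, df)
    back = read_fcs(p)
    assert back.columns[0] == sanitize_name("CD66b (granulo)") == "CD66b__granulo_"


def test_fcs_empty_table_raises(tmp_path):
    with pytest.raises(ValueError):
        write_fcs(tmp_path / "empty.fcs", pd.DataFrame({"a": []}))


def test_export_cell_table_roundtrip(tmp_path):
    table = _table(CD138=[0.9, 0.2, 0.4])
    export_cell_table(table, tmp_path / "c.fcs", tmp_path / "c.csv", ["CD138"])
    fcs = read_fcs(tmp_path / "c.fcs")
    csv = pd.read_csv(tmp_path / "c.csv")
    assert list(fcs.columns) == ["X_um", "Y_um", "CD138"]
    assert len(fcs) == len(csv) == 3
    np.testing.assert_allclose(fcs["CD138"], table["CD138"], rtol=1e-6)


def test_build_cell_table_joins_markers():
    geometry = pd.DataFrame({"id": [1, 2], "x_px": [1.0, 2.0], "y_px": [1.0, 2.0],
                             "x_um": [0.5, 1.0], "y_um": [0.5, 1.0], "area_px": [9, 9]})
    meas = pd.DataFrame({"mean_intensity": [0.7, 0.1],
                         "outside_fraction": [0.0, 0.4],
                         "excluded": [False, True]},
                        index=pd.Index([1, 2], name="id"))
    table = build_cell_table(geometry, {"CD138": meas})
    assert table.loc[table.id == 1, "CD138"].item() == 0.7
    assert bool(table.loc[table.id == 2, "excluded"].item())
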