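"""Per-cell marker measurement, FCS/CSV export, and subset gating.

For every registered marker round, the mean AEC (chromogen) amount is
measured over each segmented cell's nuclear mask intersected with the
tissue-of-interest ROI; out-of-bounds sentinel pixels (NaN from
warping) are excluded from the mean, and cells with too large a
fraction of pixels outside the ROI are flagged excluded. The resulting
cell table — unique id, x/y coordinates, area, one mean-intensity
column per marker — is exported as FCS 3.1 (with a CSV mirror) and
gated into named immune subsets by threshold expressions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from scihc.fcs import write_fcs

DEFAULT_MAX_ARTIFACT_OVERLAP = 0.25

_CLAUSE_RE = re.compile(r"^\s*([A-Za-z0-9_]+)\s*(>=|<=|>|<)\s*([-+0-9.eE]+)\s*$")


def measure_marker(
    labels: np.ndarray,
    signal: np.ndarray,
    roi: np.ndarray | None = None,
    max_artifact_overlap: float = DEFAULT_MAX_ARTIFACT_OVERLAP,
) -> pd.DataFrame:
    """Mean signal per labeled cell over valid (ROI, non-NaN) pixels.

    Returns a DataFrame indexed by cell id with columns
    ``mean_intensity``, ``outside_fraction`` (fraction of the cell's
    pixels outside the ROI or invalid) and ``excluded`` (True when that
    fraction exceeds ``max_artifact_overlap``).
    """
    labels = np.asarray(labels)
    signal = np.asarray(signal, dtype=np.float64)
    if labels.shape != signal.shape:
        raise ValueError("label image and signal channel shapes differ")
    n = int(labels.max())
    ids = np.arange(1, n + 1)
    if n == 0:
        return pd.DataFrame(
            {"mean_intensity": [], "outside_fraction": [], "excluded": []}
        )
    valid = np.isfinite(signal)
    if roi is not None:
        valid &= roi.astype(bool)
    area = ndimage.sum_labels(np.ones_like(signal), labels, index=ids)
    n_valid = ndimage.sum_labels(valid.astype(np.float64), labels, index=ids)
    sums = ndimage.sum_labels(np.where(valid, signal, 0.0), labels, index=ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    outside = 1.0 - n_valid / np.maximum(area, 1)
    return pd.DataFrame(
        {
            "mean_intensity": means,
            "outside_fraction": outside,
            "excluded": outside > max_artifact_overlap,
        },
        index=pd.Index(ids, name="id"),
    )


def build_cell_table(
    geometry: pd.DataFrame,
    marker_measurements: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Join the geometry table with per-marker measurements.

    A cell is excluded when any marker flags it (the ROI is shared
    across rounds, so flags differ only via out-of-bounds warping).
    """
    table = geometry.set_index("id")
    excluded = pd.Series(False, index=table.index)
    outside = pd.Series(0.0, index=table.index)
    for marker, meas in marker_measurements.items():
        table[marker] = meas["mean_intensity"].reindex(table.index)
        excluded |= meas["excluded"].reindex(table.index).fillna(True).astype(bool)
        outside = np.maximum(outside, meas["outside_fraction"].reindex(table.index).fillna(1.0))
    table["outside_fraction"] = outside
    table["excluded"] = excluded
    return table.reset_index()


@dataclass
class GateSet:
    """Named subsets defined by conjunctions of marker thresholds.

    Expressions are of the form ``"CD141 >= 0.5 and CD1c < 0.5"``
    (only ``and`` conjunctions of single-marker comparisons).
    """

    subsets: dict[str, str] = field(default_factory=dict)

    def clauses(self, name: str) -> list[tuple[str, str, float]]:
        out = []
        for clause in self.subsets[name].split(" and "):
            m = _CLAUSE_RE.match(clause)
            if not m:
                raise ValueError(f"cannot parse gate clause {clause!r}")
            out.append((m.group(1), m.group(2), float(m.group(3))))
        return out

    def markers(self) -> set[str]:
        return {c[0] for name in self.subsets for c in self.clauses(name)}

    @classmethod
    def default_panel(cls, thresholds: dict[str, float] | None = None, t: float = 0.5) -> "GateSet":
        """The eight standard immune subsets of the lymph-node panel."""
        th = dict(thresholds or {})

        def g(m):
            return th.get(m, t)

        return cls(
            {
                "plasmablast": f"CD138 >= {g('CD138')}",
                "pDC": f"BDCA2 >= {g('BDCA2')}",
                "cDC1": f"CD141 >= {g('CD141')} and CD1c < {g('CD1c')}",
                "cDC2": f"CD141 < {g('CD141')} and CD1c >= {g('CD1c')}",
                "sinusoidal_macrophage": f"CD169 >= {g('CD169')}",
                "non_sinusoidal_macrophage": f"CD169 < {g('CD169')} and CD68 >= {g('CD68')}",
                "NK": f"CD56 >= {g('CD56')}",
                "granulocyte": f"CD66b >= {g('CD66b')}",
            }
        )


@dataclass
class SubsetMap:
    """Assignment of cell ids (with coordinates in um) to subsets."""

    members: dict[str, pd.DataFrame]

    def ids(self, subset: str) -> np.ndarray:
        return self.members[subset]["id"].to_numpy()

    def coordinates(self, subset: str) -> pd.DataFrame:
        if subset not in self.members:
            raise KeyError(f"unknown subset {subset!r}")
        return self.members[subset][["id", "x_um", "y_um"]].sort_values(
            "id", ignore_index=True
        )


def apply_gates(table: pd.DataFrame, gates: GateSet) -> SubsetMap:
    """Gate the cell table into subsets.

    Excluded cells are skipped; a cell belongs to every subset whose
    expression its marker intensities satisfy.
    """
    usable = table
    if "excluded" in table.columns:
        usable = table[~table["excluded"].astype(bool)]
    members = {}
    for name in gates.subsets:
        mask = pd.Series(True, index=usable.index)
        for marker, op, thr in gates.clauses(name):
            if marker not in usable.columns:
                raise KeyError(f"gate {name!r} references unknown marker {marker!r}")
            col = usable[marker]
            if op == ">=":
                mask &= col >= thr
            elif op == ">":
                mask &= col > thr
            elif op == "<=":
                mask &= col <= thr
            else:
                mask &= col < thr
        members[name] = usable.loc[mask, ["id", "x_um", "y_um"]].reset_index(drop=True)
    return SubsetMap(members)


def subset_coordinates(subset_map: SubsetMap, subset: str) -> pd.DataFrame:
    """(id, x_um, y_um) of a subset's cells, ordered by id."""
    return subset_map.coordinates(subset)


def auto_threshold(intensities: np.ndarray) -> float:
    """Optional helper: bimodal (Otsu) split of a marker's intensity
    histogram. Never the default — gates are config-supplied."""
    from skimage.filters import threshold_otsu

    vals = np.asarray(intensities, dtype=np.float64)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("not enough spread to estimate a threshold")
    return float(threshold_otsu(vals))


def export_cell_table(table: pd.DataFrame, fcs_path, csv_path, markers: list[str]) -> None:
    """Write the non-excluded cells as FCS 3.1 (X_um, Y_um, markers)
    with a CSV mirror of the full table alongside."""
    keep = table
    if "excluded" in table.columns:
        keep = table[~table["excluded"].astype(bool)]
    if keep.empty:
        raise ValueError("no cells to export")
    fcs_frame = pd.DataFrame(
        {"X_um": keep["x_um"], "Y_um": keep["y_um"], **{m: keep[m] for m in markers}}
    )
    write_fcs(fcs_path, fcs_frame)
    cols = ["id", "x_um", "y_um", "area_px", *markers]
    keep[cols].to_csv(csv_path, index=False, float_format="%.6g")
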