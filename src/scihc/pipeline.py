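"""End-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis from a single run
configuration: tiling bookkeeping, per-round registration to the
hematoxylin reference, artifact/tissue masking, nucleus segmentation,
per-round chromogen measurement, FCS/CSV export, subset gating, and
spatial contact reports — writing every stage's artifacts plus a
machine-readable run manifest under the output directory. All stages
are pure functions of (inputs, config, seed), so re-running a manifest
reproduces the outputs byte for byte.

``simulate_bundle`` materializes a synthetic slide series (reference +
deformed marker rounds + ground truth) on disk in the same interchange
formats, so the full pipeline can run with no external data.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

import scihc
from scihc.image import SlideImage
from scihc.masking import MaskingRules, detect_artifacts, tissue_roi_mask
from scihc.registration import (
    RegistrationParams,
    RoundRegistration,
    register_round,
    warp_to_reference,
)
from scihc.segmentation import (
    SegmentationParams,
    StainModel,
    deconvolve_stains,
    label_to_cells,
    segment_nuclei,
)
from scihc.cytometry import (
    GateSet,
    apply_gates,
    build_cell_table,
    export_cell_table,
    measure_marker,
)
from scihc.spatial import SpatialParams, abundance_null, neighbor_statistic
from scihc.synthetic import (
    HEMATOXYLIN,
    GroundTruth,
    SimConfig,
    add_artifacts,
    deform_round,
    generate_ground_truth,
    render_round,
)
from scihc.tiling import build_tile_grid

log = logging.getLogger("scihc")


@dataclass
class RoundSpec:
    marker: str
    path: str
    round_index: int


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML/JSON-serializable."""

    reference: str
    rounds: list[RoundSpec]
    mpp: float
    out_dir: str = "scihc_out"
    tile_size: int = 512
    pyramid_levels: int = 3
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    masking: MaskingRules = field(default_factory=MaskingRules)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    stains: StainModel = field(default_factory=StainModel)
    gates: dict[str, str] = field(default_factory=dict)
    max_artifact_overlap: float = 0.25
    spatial: SpatialParams = field(default_factory=SpatialParams)
    spatial_pairs: list[tuple[str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mpp is None or self.mpp <= 0:
            raise ValueError("config requires mpp > 0")
        markers = [r.marker for r in self.rounds]
        if len(set(markers)) != len(markers):
            raise ValueError("every round needs a unique marker name")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "mpp" not in d:
            raise ValueError("config requires mpp > 0")
        rounds = [
            RoundSpec(r["marker"], r["path"], int(r.get("round", i)))
            for i, r in enumerate(d.pop("rounds", []))
        ]
        kwargs = {}
        for key, klass in (
            ("registration", RegistrationParams),
            ("masking", MaskingRules),
            ("segmentation", SegmentationParams),
            ("spatial", SpatialParams),
        ):
            if key in d:
                kwargs[key] = klass(**d.pop(key))
        if "stains" in d:
            s = d.pop("stains")
            kwargs["stains"] = StainModel(
                vectors={k: tuple(v) for k, v in s.get("vectors", {}).items()},
                background=tuple(s.get("background", (255.0, 255.0, 255.0))),
            )
        pairs = [tuple(p) for p in d.pop("spatial_pairs", [])]
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        d = {k: v for k, v in d.items() if k in known}
        return cls(rounds=rounds, spatial_pairs=pairs, **kwargs, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rounds"] = [
            {"marker": r.marker, "path": r.path, "round": r.round_index}
            for r in self.rounds
        ]
        d["stains"] = {
            "vectors": {k: list(v) for k, v in self.stains.vectors.items()},
            "background": list(self.stains.background),
        }
        return d


def load_image(path, marker: str, mpp: float) -> SlideImage:
    arr = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(arr, marker=marker, mpp=mpp)


def save_image(path, image: SlideImage) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        Image.fromarray(image.pixels).save(path)


def save_mask(path, mask: np.ndarray) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((mask.astype(np.uint8) * 255)).save(path)


def load_mask(path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


# ---------------------------------------------------------------------------
# synthetic bundle


def simulate_bundle(
    config: SimConfig,
    out_dir,
    image_format: str = "png",
    gt_override: GroundTruth | None = None,
) -> tuple[GroundTruth, RunConfig]:
    """Render and write a full synthetic slide series plus ground truth,
    and return a ready-to-run pipeline configuration for it.

    ``gt_override`` lets callers modify the generated truth (e.g. plant
    spatial contacts) before rendering.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = gt_override if gt_override is not None else generate_ground_truth(config)

    ref = render_round(gt, HEMATOXYLIN, config)
    artifact_truth: dict[str, np.ndarray] = {}
    if config.artifacts:
        ref, artifact_truth = add_artifacts(ref, config.artifacts)
    ref_path = out / f"reference_hematoxylin.{image_format}"
    save_image(ref_path, ref)

    rounds = []
    for r, marker in enumerate(config.markers):
        img = deform_round(render_round(gt, marker, config), gt, r)
        p = out / f"round{r:02d}_{marker}.{image_format}"
        save_image(p, img)
        rounds.append({"marker": marker, "path": str(p), "round": r})

    # ground truth: cells as JSON+CSV, deformations as JSON, masks as PNG
    gt.cells.to_csv(out / "truth_cells.csv", index=False, float_format="%.6g")
    truth = {
        "seed": gt.seed,
        "per_round_shift": {str(k): list(v) for k, v in gt.per_round_shift.items()},
        "per_round_field": {
            str(k): f.to_dict() for k, f in gt.per_round_field.items()
        },
    }
    (out / "truth_deformations.json").write_text(json.dumps(truth, indent=1))
    for name, mask in artifact_truth.items():
        save_mask(out / f"truth_mask_{name}.png", mask)
        gt.artifact_masks[name] = mask

    markers = list(config.markers)
    run = RunConfig(
        reference=str(ref_path),
        rounds=[RoundSpec(r["marker"], r["path"], r["round"]) for r in rounds],
        mpp=config.mpp,
        out_dir=str(out / "analysis"),
        stains=StainModel(
            vectors={
                "hematoxylin": tuple(config.hematoxylin_rgb),
                "aec": tuple(config.aec_rgb),
            },
            background=tuple(float(c) for c in config.background),
        ),
        gates=dict(GateSet.default_panel(t=0.3).subsets)
        if set(markers) >= {"CD138", "BDCA2", "CD141", "CD1c", "CD169", "CD68", "CD56", "CD66b"}
        else {f"{m}_pos": f"{m} >= 0.3" for m in markers},
        seed=config.seed,
    )
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(run.to_dict(), fh, sort_keys=False)
    return gt, run


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": scihc.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "valid": False,
    }
    t_start = time.time()
    stage = "load"
    try:
        reference = load_image(config.reference, HEMATOXYLIN, config.mpp)
        grid = build_tile_grid(reference.width, reference.height, config.tile_size)
        manifest["stages"]["tiling"] = {
            "n_tiles": grid.n_tiles,
            "tile_size": grid.tile_size,
            "levels": config.pyramid_levels,
        }

        stage = "masking"
        t0 = time.time()
        artifacts = detect_artifacts(reference, config.masking)
        roi = tissue_roi_mask(reference, artifacts, config.masking)
        for name, mask in artifacts.items():
            save_mask(out / "masks" / f"{name}.png", mask)
        save_mask(out / "masks" / "tissue_of_interest.png", roi)
        manifest["stages"]["masking"] = {
            "roi_px": int(roi.sum()),
            **{f"{k}_px": int(v.sum()) for k, v in artifacts.items()},
            "seconds": round(time.time() - t0, 2),
        }
        log.info("masking done: ROI %d px", int(roi.sum()))

        stage = "segmentation"
        t0 = time.time()
        stains_ref = deconvolve_stains(reference.pixels, config.stains)
        labels = segment_nuclei(stains_ref["hematoxylin"], roi, config.segmentation)
        geometry = label_to_cells(labels, config.mpp)
        tifffile.imwrite(out / "labels.tif", labels.astype(np.int32))
        geometry.to_csv(out / "cells_geometry.csv", index=False, float_format="%.6g")
        manifest["stages"]["segmentation"] = {
            "n_cells": int(len(geometry)),
            "seconds": round(time.time() - t0, 2),
        }
        log.info("segmentation done: %d cells", len(geometry))

        stage = "registration"
        measurements: dict[str, pd.DataFrame] = {}
        reg_dir = out / "registration"
        reg_dir.mkdir(exist_ok=True)
        for spec in sorted(config.rounds, key=lambda r: r.round_index):
            t0 = time.time()
            moving = load_image(spec.path, spec.marker, config.mpp)
            reg = register_round(reference, moving, config.registration)
            warped = warp_to_reference(moving, reg.rigid, reg.field)
            info = {
                "rigid": {"dx": reg.rigid.dx, "dy": reg.rigid.dy, "score": reg.rigid.score},
                "n_candidates": reg.n_candidates,
                "n_accepted": len(reg.points),
                "field": reg.field.to_dict() if reg.field else None,
            }
            (reg_dir / f"{spec.marker}_field.json").write_text(json.dumps(info, indent=1))
            if reg.field is not None:
                dense = reg.field.dense()[:, ::16, ::16].astype(np.float32)
                tifffile.imwrite(reg_dir / f"{spec.marker}_displacement.tif", dense)
            log.info(
                "registered %s: rigid=(%.1f, %.1f) accepted %d/%d in %.1fs",
                spec.marker, reg.rigid.dx, reg.rigid.dy,
                len(reg.points), reg.n_candidates, time.time() - t0,
            )

            stage = f"measurement[{spec.marker}]"
            stains = deconvolve_stains(warped, config.stains)
            measurements[spec.marker] = measure_marker(
                labels, stains["aec"], roi, config.max_artifact_overlap
            )
            manifest["stages"][f"round_{spec.marker}"] = {
                **info,
                "field": None,  # full field already on disk
                "seconds": round(time.time() - t0, 2),
            }

        stage = "cytometry"
        table = build_cell_table(geometry, measurements)
        markers = [r.marker for r in sorted(config.rounds, key=lambda r: r.round_index)]
        export_cell_table(table, out / "cells.fcs", out / "cells.csv", markers)
        table.to_csv(out / "cells_full.csv", index=False, float_format="%.6g")
        manifest["stages"]["cytometry"] = {
            "n_cells": int(len(table)),
            "n_excluded": int(table["excluded"].sum()),
        }

        stage = "gating"
        gates = GateSet(dict(config.gates)) if config.gates else GateSet.default_panel()
        subset_map = apply_gates(table, gates)
        sub_dir = out / "subsets"
        sub_dir.mkdir(exist_ok=True)
        counts = {}
        for name in gates.subsets:
            coords = subset_map.coordinates(name)
            coords.to_csv(sub_dir / f"{name}.csv", index=False, float_format="%.6g")
            counts[name] = int(len(coords))
        manifest["stages"]["gating"] = counts
        log.info("gating done: %s", counts)

        stage = "spatial"
        pairs = config.spatial_pairs or _default_pairs(counts)
        spatial_dir = out / "spatial"
        spatial_dir.mkdir(exist_ok=True)
        sp_summary = {}
        non_excluded = table[~table["excluded"].astype(bool)]
        for query, target in pairs:
            q = subset_map.coordinates(query)
            t = subset_map.coordinates(target)
            if q.empty or t.empty:
                continue
            stats = neighbor_statistic(
                q[["x_um", "y_um"]].to_numpy(),
                t[["x_um", "y_um"]].to_numpy(),
                config.spatial,
                query_ids=q["id"].to_numpy(),
                target_ids=t["id"].to_numpy(),
            )
            stats.per_cell.to_csv(
                spatial_dir / f"{query}_vs_{target}.csv", index=False,
                float_format="%.6g",
            )
            pool = non_excluded[~non_excluded["id"].isin(q["id"])]
            report = stats.to_report()
            if config.spatial.permutations >= 1 and len(pool) >= len(t):
                _, p, obs = abundance_null(
                    q[["x_um", "y_um"]].to_numpy(),
                    t[["x_um", "y_um"]].to_numpy(),
                    pool[["x_um", "y_um"]].to_numpy(),
                    config.spatial,
                    query_ids=q["id"].to_numpy(),
                    pool_ids=pool["id"].to_numpy(),
                    target_ids=t["id"].to_numpy(),
                )
                report["abundance_null_p"] = p
            (spatial_dir / f"{query}_vs_{target}.json").write_text(
                json.dumps(report, indent=1)
            )
            sp_summary[f"{query}_vs_{target}"] = report
        manifest["stages"]["spatial"] = sp_summary

        manifest["valid"] = True
    except Exception as exc:
        manifest["error"] = {"stage": stage, "cause": repr(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    manifest["seconds_total"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _default_pairs(counts: dict[str, int]) -> list[tuple[str, str]]:
    """Plasmablasts vs every other non-empty subset, when present."""
    if "plasmablast" not in counts:
        names = [n for n, c in counts.items() if c > 0]
        return [(names[0], t) for t in names[1:]] if len(names) > 1 else []
    return [
        ("plasmablast", t)
        for t, c in counts.items()
        if t != "plasmablast" and c > 0
    ]
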