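"""Batch orchestration: configuration, staged runs, statistics export.

A run processes a list of images through the prefix-closed stage chain

    segment -> preprocess -> detect -> classify -> coloc -> export

writing per-image artifacts (16-bit label mask TIFF, outline/candidate/foci
JSON, per-cell statistics CSV) into a run directory. Every JSON artifact
embeds the resolved-configuration content hash; re-runs with an unchanged
hash skip completed stages unless forced, and equal hashes produce
byte-identical JSON outputs. Physical parameters (contour length bounds,
cell radii) are configured in nm and converted to px through the pixel
size, so one configuration transfers across magnifications.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classify as _classify
from .contours import detect_foci
from .features import FEATURE_NAMES, extract_features, feature_matrix, rank_brightness
from .preprocess import denoise, extract_cells, max_project
from .segmentation import SegmentationParams, outline_from_mask, segment_cells

log = logging.getLogger("puncta")

STAGES = ["segment", "preprocess", "detect", "classify", "coloc", "export"]


@dataclass
class ImageEntry:
    name: str
    brightfield: str | None = None
    stack: str | None = None
    stack2: str | None = None  # optional second channel for colocalization
    mask: str | None = None  # precomputed label mask bypasses segmentation


@dataclass
class RunConfig:
    images: list[ImageEntry] = field(default_factory=list)
    outdir: str = "run"
    pixel_size_nm: float = 40.7
    # segmentation
    frangi_scales: tuple[float, float] = (1.0, 3.0)
    frangi_threshold: float = 0.05
    black_ridges: bool = False
    min_blob: float = 40.0
    eccentricity_bounds: tuple[float, float] = (0.0, 1.0)
    solidity_bounds: tuple[float, float] = (0.0, 1.0)
    r_min_nm: float = 325.6  # 8 px at 40.7 nm/px
    r_max_nm: float = 1221.0
    angular_coverage_min: float = 0.75
    min_cell_area_px: float = 80.0
    # preprocessing
    nlm_patch_size: int = 5
    nlm_patch_distance: int = 6
    nlm_strength: float = 0.0
    # foci detection
    L_min_nm: float = 244.2  # 6 px
    L_max_nm: float = 3256.0  # 80 px
    n_levels: int = 64
    n_eval: int = 32
    area_scale: float = 1.0
    # classification
    model_path: str | None = None
    labels_path: str | None = None
    overrides_path: str | None = None
    threshold_bounds: dict = field(default_factory=dict)
    svm_C: float = 1.0
    svm_gamma: float | str = "scale"
    grid_search: bool = False
    cv_folds: int = 6
    seed: int = 0

    @property
    def pixel_size(self) -> float:
        return self.pixel_size_nm

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["images"] = [
            ImageEntry(**e) if isinstance(e, dict) else e for e in d.get("images", [])
        ]
        for key in ("frangi_scales", "eccentricity_bounds", "solidity_bounds"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def segmentation_params(self) -> SegmentationParams:
        px = self.pixel_size_nm
        return SegmentationParams(
            frangi_scales=self.frangi_scales,
            frangi_threshold=self.frangi_threshold,
            black_ridges=self.black_ridges,
            min_blob=self.min_blob,
            eccentricity_bounds=self.eccentricity_bounds,
            solidity_bounds=self.solidity_bounds,
            r_min=self.r_min_nm / px,
            r_max=self.r_max_nm / px,
            angular_coverage_min=self.angular_coverage_min,
            min_area=self.min_cell_area_px,
        )


def _write_json(path: Path, payload: dict, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **payload}
    path.write_text(json.dumps(payload, sort_keys=True, indent=1))


def _stage_done(path: Path, config_hash: str) -> bool:
    if not path.exists():
        return False
    try:
        return json.loads(path.read_text()).get("config_hash") == config_hash
    except (json.JSONDecodeError, AttributeError):
        return False


def _load_image(path: str) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def _outline_payload(outlines) -> dict:
    return {
        "cells": [
            {
                "polygon": np.round(o.polygon, 4).tolist(),
                "centroid": [round(float(c), 4) for c in o.centroid],
                "area_px2": round(float(o.area), 4),
            }
            for o in outlines
        ]
    }


def _foci_payload(all_foci, pixel_size: float) -> dict:
    return {
        "cells": [
            {
                "foci": [
                    {
                        "polygon": np.round(f.contour.vertices, 4).tolist(),
                        "level": round(float(f.contour.level), 6),
                        "area_px2": round(float(f.area), 4),
                        "area_nm2": round(float(f.area) * pixel_size**2, 2),
                        "centroid": [round(float(c), 4) for c in f.centroid],
                        "raw_max": round(float(f.intensity_max), 4),
                        "raw_min": round(float(f.intensity_min), 4),
                        "raw_mean": round(float(f.intensity_mean), 4),
                    }
                    for f in cell_foci
                ]
            }
            for cell_foci in all_foci
        ]
    }


def _run_one_image(
    entry: ImageEntry, config: RunConfig, outdir: Path, stages: list[str], force: bool
) -> None:
    chash = config.content_hash()
    imgdir = outdir / entry.name
    imgdir.mkdir(parents=True, exist_ok=True)
    px = config.pixel_size_nm

    outlines = None
    if "segment" in stages:
        seg_json = imgdir / "outlines.json"
        if force or not _stage_done(seg_json, chash):
            if entry.mask is not None:
                labels = np.asarray(tifffile.imread(entry.mask))
                outlines = [
                    outline_from_mask(labels == k)
                    for k in np.unique(labels)
                    if k != 0
                ]
            else:
                if entry.brightfield is None:
                    raise FileNotFoundError(f"{entry.name}: no brightfield or mask")
                bf = _load_image(entry.brightfield)
                outlines = segment_cells(bf, config.segmentation_params())
            label_img = np.zeros(
                outlines[0].mask.shape if outlines else (1, 1), dtype=np.uint16
            )
            for k, o in enumerate(outlines, start=1):
                label_img[o.mask] = k
            tifffile.imwrite(imgdir / "mask.tif", label_img)
            _write_json(seg_json, _outline_payload(outlines), chash)
        else:
            log.info("%s: segment up to date, skipping", entry.name)

    if not set(stages) & {"preprocess", "detect", "classify", "coloc", "export"}:
        return

    # later stages recompute in memory from the stored mask
    label_img = np.asarray(tifffile.imread(imgdir / "mask.tif"))
    outlines = [outline_from_mask(label_img == k) for k in np.unique(label_img) if k]
    if entry.stack is None:
        return
    stack = _load_image(entry.stack)
    projected = denoise(
        max_project(stack),
        patch_size=config.nlm_patch_size,
        patch_distance=config.nlm_patch_distance,
        strength=config.nlm_strength,
    )
    regions = extract_cells(projected, outlines, pixel_size=px)

    if not set(stages) & {"detect", "classify", "coloc", "export"}:
        return

    L_min = config.L_min_nm / px
    L_max = config.L_max_nm / px
    all_candidates, all_foci, all_vectors = [], [], []
    for region in regions:
        candidates, foci = detect_foci(
            region,
            L_min,
            L_max,
            n_levels=config.n_levels,
            n_eval=config.n_eval,
            area_scale=config.area_scale,
        )
        vectors = []
        kept_foci = []
        for focus in foci:
            cand = candidates[focus.source_candidates[0]]
            vec = extract_features(cand, focus, region)
            if vec is not None:
                vectors.append(vec)
                kept_foci.append(focus)
        rank_brightness(vectors)
        all_candidates.append(candidates)
        all_foci.append(kept_foci)
        all_vectors.append(vectors)

    detect_json = imgdir / "foci.json"
    if force or not _stage_done(detect_json, chash):
        _write_json(detect_json, _foci_payload(all_foci, px), chash)

    if not set(stages) & {"classify", "coloc", "export"}:
        return

    flat_vectors = [v for vecs in all_vectors for v in vecs]
    cell_ids = np.concatenate(
        [np.full(len(vecs), i) for i, vecs in enumerate(all_vectors)]
        or [np.empty(0, dtype=int)]
    ).astype(int)
    if flat_vectors:
        X = feature_matrix(flat_vectors)
        if config.model_path:
            model = _classify.FocusSVC.load(config.model_path)
            labels, _ = _classify.predict(model, X, cell_ids=cell_ids)
        elif config.threshold_bounds:
            bounds = {
                k: tuple(v) for k, v in config.threshold_bounds.items()
            }
            labels = _classify.threshold_classify(X, bounds)
        else:
            labels = np.ones(len(X), dtype=int)
        if config.overrides_path:
            overrides = json.loads(Path(config.overrides_path).read_text())
            for key, lab in overrides.items():
                labels[int(key)] = int(lab)
    else:
        labels = np.empty(0, dtype=int)

    labels_json = imgdir / "labels.json"
    _write_json(
        labels_json,
        {
            "labels": labels.tolist(),
            "cell_ids": cell_ids.tolist(),
            "features": [
                dict(zip(FEATURE_NAMES, np.round(v.to_array(), 6).tolist()))
                for v in flat_vectors
            ],
        },
        chash,
    )

    if "coloc" in stages and entry.stack2 is not None:
        from .coloc import colocalize_cell

        projected2 = denoise(
            max_project(_load_image(entry.stack2)),
            patch_size=config.nlm_patch_size,
            patch_distance=config.nlm_patch_distance,
            strength=config.nlm_strength,
        )
        regions2 = extract_cells(projected2, outlines, pixel_size=px)
        coloc_cells = []
        for cid, (r1, r2) in enumerate(zip(regions, regions2)):
            _, foci2 = detect_foci(
                r2,
                L_min,
                L_max,
                n_levels=config.n_levels,
                n_eval=config.n_eval,
                area_scale=config.area_scale,
            )
            rec = colocalize_cell(cid, r1, r2, all_foci[cid], foci2)
            coloc_cells.append(
                {
                    "cell_id": cid,
                    "pearson": None if rec.pearson is None else round(rec.pearson, 6),
                    "pairs": [
                        {k: (round(v, 4) if isinstance(v, float) else v) for k, v in p.scaled(px).items()}
                        for p in rec.pairs
                    ],
                    "nearest_in_b": {str(k): v for k, v in rec.nearest_in_b.items()},
                    "nearest_in_a": {str(k): v for k, v in rec.nearest_in_a.items()},
                }
            )
        _write_json(imgdir / "coloc.json", {"cells": coloc_cells}, chash)

    if "export" in stages:
        per_cell_foci = []
        offset = 0
        for vecs, foci in zip(all_vectors, all_foci):
            n = len(vecs)
            keep = labels[offset : offset + n].astype(bool)
            per_cell_foci.append([f for f, k in zip(foci, keep) if k])
            offset += n
        detail, summary = export_stats(per_cell_foci, pixel_size=px)
        detail.to_csv(imgdir / "foci_stats.csv", index=False)
        summary.to_csv(imgdir / "summary.csv", index=False)


def run_pipeline(
    config: RunConfig, stages: list[str] | None = None, force: bool = False
) -> Path:
    """Run the staged pipeline over every configured image.

    ``stages`` must be a prefix-closed subset of
    ``segment, preprocess, detect, classify, coloc, export``. Per-image
    failures are logged and skipped; the run fails only if every image
    fails.
    """
    stages = stages or list(STAGES)
    idx = [STAGES.index(s) for s in stages]
    if sorted(idx) != list(range(max(idx) + 1)):
        raise ValueError(f"stages must be a prefix of {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(
            {"config_hash": config.content_hash(), **config.to_dict()},
            sort_keys=True,
            indent=1,
            default=str,
        )
    )
    failures = 0
    for entry in config.images:
        try:
            _run_one_image(entry, config, outdir, stages, force)
        except Exception:  # noqa: BLE001 - per-file failures must not abort the batch
            log.exception("image %s failed", entry.name)
            failures += 1
    if config.images and failures == len(config.images):
        raise RuntimeError("all images failed")
    return outdir


def export_stats(
    foci_per_cell: list[list], pixel_size: float = 40.7
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-focus detail rows plus whole-run summary statistics.

    Detail: one row per focus (cell id, area in px^2/nm^2, raw mean/max/min
    brightness — unnormalized microscope values). Summary: foci counts per
    cell, mean foci per cell, and the percentage of cells with at least one
    focus.
    """
    rows = []
    for cell_id, foci in enumerate(foci_per_cell):
        for k, f in enumerate(foci):
            rows.append(
                {
                    "cell_id": cell_id,
                    "focus_id": k,
                    "area_px2": f.area,
                    "area_nm2": f.area * pixel_size**2,
                    "equivalent_radius_nm": f.equivalent_radius * pixel_size,
                    "raw_mean": f.intensity_mean,
                    "raw_max": f.intensity_max,
                    "raw_min": f.intensity_min,
                }
            )
    detail = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "focus_id",
            "area_px2",
            "area_nm2",
            "equivalent_radius_nm",
            "raw_mean",
            "raw_max",
            "raw_min",
        ],
    )
    n_cells = len(foci_per_cell)
    counts = [len(f) for f in foci_per_cell]
    summary = pd.DataFrame(
        [
            {
                "n_cells": n_cells,
                "n_foci": int(sum(counts)),
                "mean_foci_per_cell": float(np.mean(counts)) if n_cells else 0.0,
                "pct_cells_with_foci": (
                    100.0 * sum(c > 0 for c in counts) / n_cells if n_cells else 0.0
                ),
            }
        ]
    )
    return detail, summary
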