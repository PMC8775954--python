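"""End-to-end orchestration: config validation, staged runs, manifest.

A run composes the stages in order — (synthetic generation) →
segmentation → quadrant morphometry with edge removal → shape-mode model
fit + assignment → frequency / fold-change tables + heatmaps →
Kruskal–Wallis/Dunn statistics — writing every artifact under one output
directory (subdirs ``masks/``, ``features/``, ``model/``, ``stats/``,
``figures/``) with a content-hash manifest and a run log.

Reproducibility: a single global seed is fanned out to per-stage child
seeds by stable hashing of stage names, so a stage rerun from on-disk
intermediates reproduces the composed run bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from gliamorph import morphometry, population, shape_modes, synthetic
from gliamorph.segmentation import SegmentationConfig, segment

log = logging.getLogger("gliamorph")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, manifest: dict):
        self.stage = stage
        self.partial_manifest = manifest
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """Validated configuration of a full run."""

    mode: str = "synthetic"  # or "image-dir"
    output_dir: str = "gliamorph_run"
    image_dir: str | None = None
    design_csv: str | None = None
    seed: int = 0
    pixel_size_um: float = 1.0
    # synthetic-mode knobs
    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 25
    n_images_per_condition: int = 2
    noise_sd: float = 0.02
    # segmentation
    segmentation: SegmentationConfig = field(
        default_factory=lambda: SegmentationConfig(pixel_size_um=1.0))
    # shape modes
    k: int = 5
    n_points: int = 50
    train_fraction: float = 0.8
    # statistics
    alpha: float = 0.05
    adjustment: str = "bonferroni"
    fold_change_statistic: str = "median"
    control_group: str = "healthy"


def validate_config(raw: dict | str | Path) -> PipelineConfig:
    """Build a :class:`PipelineConfig`, reporting every violation at once."""
    if isinstance(raw, (str, Path)):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    errors: list[str] = []
    raw = dict(raw)
    seg_raw = raw.pop("segmentation", {})
    known = set(PipelineConfig.__dataclass_fields__)
    for key in set(raw) - known:
        errors.append(f"unknown option {key!r}")
        raw.pop(key)
    mode = raw.get("mode", "synthetic")
    if mode not in ("synthetic", "image-dir"):
        errors.append(f"mode must be 'synthetic' or 'image-dir', got {mode!r}")
    if mode == "image-dir":
        for key in ("image_dir", "design_csv"):
            val = raw.get(key)
            if not val:
                errors.append(f"{key} is required in image-dir mode")
            elif not Path(val).exists():
                errors.append(f"{key} path does not exist: {val}")
    if raw.get("k", 5) < 2:
        errors.append("k must be >= 2")
    if raw.get("n_points", 50) < 3:
        errors.append("n_points must be >= 3")
    if not (0 < raw.get("train_fraction", 0.8) <= 1):
        errors.append("train_fraction must be in (0, 1]")
    if raw.get("pixel_size_um", 1.0) <= 0:
        errors.append("pixel_size_um must be positive")
    if raw.get("n_cells", 25) < 0:
        errors.append("n_cells must be >= 0")
    if not (0 < raw.get("alpha", 0.05) < 1):
        errors.append("alpha must be in (0, 1)")
    if raw.get("adjustment", "bonferroni") not in ("bonferroni", "holm", "none"):
        errors.append("adjustment must be bonferroni, holm or none")
    if raw.get("fold_change_statistic", "median") not in ("median", "mean"):
        errors.append("fold_change_statistic must be median or mean")
    try:
        seg = SegmentationConfig(
            pixel_size_um=raw.get("pixel_size_um", 1.0), **seg_raw)
    except (TypeError, ValueError) as exc:
        errors.append(f"segmentation: {exc}")
        seg = SegmentationConfig()
    if "image_shape" in raw:
        raw["image_shape"] = tuple(raw["image_shape"])
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(segmentation=seg, **raw)


def stage_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31)."""
    return (zlib.crc32(stage.encode()) ^ (base_seed * 2654435761
                                          & 0x7FFFFFFF)) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; return the artifact manifest."""
    out = Path(config.output_dir)
    for sub in ("masks", "features", "model", "stats", "figures", "images"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict = {"artifacts": {}, "config": _config_dict(config),
                      "seed": config.seed}
    arts = manifest["artifacts"]
    stage = "input"
    try:
        log.info("run starting with seed %d", config.seed)
        # ---- input stage
        if config.mode == "synthetic":
            design_rows = synthetic.default_study_design(
                config.n_images_per_condition)
            base = synthetic.SyntheticSpec(
                image_shape=config.image_shape,
                pixel_size_um=config.pixel_size_um,
                n_cells=config.n_cells, noise_sd=config.noise_sd)
            records, design = synthetic.generate_condition_series(
                design_rows, base, stage_seed(config.seed, "simulate"),
                out_dir=out / "images")
            arts.setdefault("images", []).append(str(out / "images"))
        else:
            design = pd.read_csv(config.design_csv)
            records = []
            for _, row in design.iterrows():
                path = Path(config.image_dir) / Path(row["image_path"]).name
                img = tifffile.imread(path).astype(float)
                if img.max() > 1:
                    img = img / (255.0 if img.max() <= 255 else 65535.0)
                records.append({"image_id": row.get("image_id",
                                                    Path(path).stem),
                                "group": row["group"],
                                "exposure_h": row["exposure_h"],
                                "dose_ug": row.get("dose_ug", 0.0),
                                "image": img})
            if "image_id" not in design.columns:
                design["image_id"] = [r["image_id"] for r in records]

        # ---- segmentation + morphometry
        stage = "segment"
        all_cells: list = []
        masks = {}
        for rec in records:
            mask = segment(rec["image"], config.segmentation,
                           source=rec["image_id"])
            masks[rec["image_id"]] = mask
            mpath = out / "masks" / f"{rec['image_id']}_mask.tif"
            tifffile.imwrite(mpath, mask.labels.astype(np.uint16))
            arts.setdefault("masks", []).append(str(mpath))

        stage = "features"
        per_image_cells = {}
        for rec in records:
            cells = morphometry.measure_quadrants(
                masks[rec["image_id"]], config.pixel_size_um,
                image_id=rec["image_id"])
            per_image_cells[rec["image_id"]] = cells
            all_cells.extend(cells)
        features = morphometry.records_to_dataframe(all_cells)

        # ---- shape modes
        stage = "shapemodes"
        contours, ids, imgs, areas = [], [], [], []
        for rec in records:
            labels = masks[rec["image_id"]].labels
            for q, tile in enumerate(
                    morphometry.split_quadrants(labels), start=1):
                from skimage.measure import label as _label
                rel = _label(tile > 0, connectivity=2)
                kept = {c.label for c in per_image_cells[rec["image_id"]]
                        if c.quadrant == str(q) and not c.degenerate}
                for lab in sorted(kept):
                    try:
                        cont = shape_modes.extract_contour(rel == lab)
                    except shape_modes.ParameterError:
                        continue
                    contours.append(cont)
                    ids.append(f"{rec['image_id']}:q{q}:{lab}")
                    imgs.append(rec["image_id"])
                    areas.append(int((rel == lab).sum()))
        analysis = shape_modes.ShapeModeAnalysis(
            contours, cell_ids=ids, image_ids=imgs, areas=areas,
            k=config.k, n_points=config.n_points,
            train_fraction=config.train_fraction)
        results = analysis.fit(seed=stage_seed(config.seed, "shapemodes"))
        model_path = out / "model" / "shape_mode_model.json"
        results.model.to_json(model_path)
        arts.setdefault("model", []).append(str(model_path))
        (out / "model" / "summary.txt").write_text(results.summary())

        assign = results.assignments.copy()
        fpath = out / "features" / "cells.csv"
        key = (features["image_id"] + ":q" + features["quadrant"]
               + ":" + features["label"].astype(str))
        mode_map = dict(zip(assign["cell_id"], assign["shape_mode"]))
        split_map = dict(zip(assign["cell_id"], assign["split"]))
        merged_features = features.copy()
        merged_features["shape_mode"] = key.map(mode_map)
        merged_features["split"] = key.map(split_map)
        merged_features.to_csv(fpath, index=False)
        arts.setdefault("features", []).append(str(fpath))

        # ---- population tables
        stage = "stats"
        freq = population.sm_frequencies(assign, design, k=config.k)
        freq_csv = out / "stats" / "sm_frequencies.csv"
        population.heatmap_export(
            freq.drop(columns="n"), "frequency",
            out / "figures" / "sm_frequencies.png", freq_csv)
        arts.setdefault("tables", []).append(str(freq_csv))
        arts.setdefault("figures", []).append(
            str(out / "figures" / "sm_frequencies.png"))

        cells_design = merged_features.dropna(subset=["aspect_ratio"])
        fold = population.feature_fold_change(
            cells_design, design, control_group=config.control_group,
            statistic=config.fold_change_statistic)
        fold_csv = out / "stats" / "fold_change.csv"
        population.heatmap_export(
            fold, "fold_change", out / "figures" / "fold_change.png",
            fold_csv)
        arts.setdefault("tables", []).append(str(fold_csv))
        arts.setdefault("figures", []).append(
            str(out / "figures" / "fold_change.png"))

        report_lines = []
        stat_rows = []
        times = sorted(design["exposure_h"].unique())
        for feat in population.FEATURES:
            for t in times:
                res = population.compare_feature(
                    cells_design, design, feat, exposure_h=t,
                    adjustment=config.adjustment)
                stat_rows.append({"feature": feat, "exposure_h": t,
                                  "H": res.statistic, "p": res.pvalue})
                report_lines.append(
                    f"{feat} @ {t} h: H = {res.statistic:.3f}, "
                    f"p = {res.pvalue:.3g}")
                for _, pr in res.pairwise.iterrows():
                    report_lines.append(
                        f"    {pr['group_a']} vs {pr['group_b']}: "
                        f"z = {pr['z']:.3f}, adj p = {pr['p_adj']:.3g}")
        stats_csv = out / "stats" / "kruskal_dunn.csv"
        pd.DataFrame(stat_rows).to_csv(stats_csv, index=False)
        (out / "stats" / "report.txt").write_text("\n".join(report_lines))
        arts.setdefault("stats", []).extend(
            [str(stats_csv), str(out / "stats" / "report.txt")])

        # ---- overlays
        stage = "figures"
        first = records[0]["image_id"]
        whole_cells = morphometry.extract_cells(masks[first], config.pixel_size_um,
                                                image_id=first)
        whole_assign = {}
        for c in whole_cells:
            if c.degenerate:
                continue
            try:
                cont = shape_modes.extract_contour(
                    masks[first].labels == c.label)
            except shape_modes.ParameterError:
                continue
            mode, _ = results.model.assign(cont)
            whole_assign[c.label] = mode
        overlay = shape_modes.render_mode_overlay(masks[first], whole_assign,
                                                  k=config.k)
        opath = out / "figures" / f"{first}_modes.png"
        import imageio.v3 as iio
        iio.imwrite(opath, overlay)
        arts.setdefault("figures", []).append(str(opath))

        # ---- manifest
        hashes = {}
        for paths in arts.values():
            for p in paths:
                pth = Path(p)
                if pth.is_file():
                    hashes[str(pth.relative_to(out))] = _sha256(pth)
                elif pth.is_dir():
                    for f in sorted(pth.rglob("*")):
                        if f.is_file():
                            hashes[str(f.relative_to(out))] = _sha256(f)
        manifest["hashes"] = hashes
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        log.info("run complete: %d artifacts", len(hashes))
        return manifest
    except Exception as exc:  # noqa: BLE001 - report failing stage
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc, manifest) from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["segmentation"] = asdict(config.segmentation)
    return d
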