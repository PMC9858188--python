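"""End-to-end slide scoring and evaluation runners.

``run_slide`` ties the three stages together: tissue masking on a
low-resolution level, tumor-tile detection with the configured classifier
backend, and per-tile index measurement aggregated into a slide score by
both the staining-only and integrated methods.  Outputs are a JSON report,
a per-tile feature CSV, a tumor-probability heatmap overlay and stain/cell
overlays for the densest tiles.
"""
from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from matplotlib import colormaps
from skimage.morphology import dilation, disk
from skimage.transform import resize

from . import evaluation
from .cells import measure_patch
from .config import PipelineConfig
from .detection import (
    HeuristicClassifier,
    PatchClassifier,
    SklearnPatchClassifier,
    binarize_map,
    probability_map,
)
from .errors import InvalidInputError, NoTumorTilesError
from .masking import enumerate_tiles, tissue_mask
from .scoring import (
    SlideScore,
    aggregate_slide,
    classify_integrated,
    classify_staining_only,
    patch_features,
)
from .slide_io import Pyramid
from .types import BinaryMask, RgbImage

log = logging.getLogger("her2quant")


@dataclass
class SlideReport:
    """Everything ``run_slide`` computed for one slide."""

    ihc_class: str
    her2_status: str
    ish_reflex: bool
    staining_only: SlideScore | None
    integrated: SlideScore | None
    slide_features: dict
    tile_table: pd.DataFrame
    n_tissue_tiles: int
    n_tumor_tiles: int
    indeterminate: bool = False
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "ihc_class": self.ihc_class,
            "her2_status": self.her2_status,
            "ish_reflex": self.ish_reflex,
            "indeterminate": self.indeterminate,
            "slide_features": self.slide_features,
            "votes": self.integrated.votes if self.integrated else {},
            "staining_only_class": self.staining_only.ihc_class
            if self.staining_only
            else None,
            "n_tissue_tiles": self.n_tissue_tiles,
            "n_tumor_tiles": self.n_tumor_tiles,
            "provenance": self.provenance,
        }


def make_classifier(config: PipelineConfig) -> PatchClassifier:
    if config.classifier_backend == "heuristic":
        return HeuristicClassifier(brown=config.brown_range())
    if config.classifier_backend in ("mlp", "external"):
        if not config.checkpoint:
            raise InvalidInputError(
                f"backend {config.classifier_backend!r} needs a checkpoint path"
            )
        return SklearnPatchClassifier.load(config.checkpoint)
    raise InvalidInputError(f"unknown classifier backend {config.classifier_backend!r}")


def choose_mask_level(slide: Pyramid, max_side: int = 2048) -> int:
    """Highest-resolution level whose longest side fits in ``max_side``."""
    for level, (h, w) in enumerate(slide.level_dimensions):
        if max(h, w) <= max_side:
            return level
    return slide.n_levels - 1


def _scoring_tiles(
    mask_512, pmap, tumor_tiles: BinaryMask, config: PipelineConfig
) -> list[tuple[int, int]]:
    """512-tile origins whose 256-tile footprint is mostly tumor."""
    ratio = config.score_tile_size // config.classify_tile_size
    tm = tumor_tiles.pixels
    origins = []
    for r0, c0, _ in mask_512.tiles:
        i, j = r0 // config.classify_tile_size, c0 // config.classify_tile_size
        block = tm[i : i + ratio, j : j + ratio]
        if block.size and block.mean() >= config.tumor_tile_fraction:
            origins.append((r0, c0))
    return origins


def run_slide(
    slide: Pyramid | str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    top_k_overlays: int = 2,
) -> SlideReport:
    """Score one slide end to end; deterministic given config and inputs."""
    config = config or PipelineConfig()
    if not isinstance(slide, Pyramid):
        slide = Pyramid.open(slide)
    t0 = datetime.datetime.now()

    level = choose_mask_level(slide, config.mask_max_side)
    mask = tissue_mask(
        RgbImage(slide.levels[level], level=level, downsample=2**level),
        combine=config.hs_combine,
    )
    grid = enumerate_tiles(mask, config.classify_tile_size, config.min_tissue_fraction)
    log.info("tissue mask: level %d, %d tiles kept", level, len(grid))

    provenance = {
        "config_hash": config.digest(),
        "version": config.version,
        "timestamp": t0.isoformat(),
    }
    if not grid.tiles:
        report = SlideReport(
            ihc_class="indeterminate",
            her2_status="indeterminate",
            ish_reflex=False,
            staining_only=None,
            integrated=None,
            slide_features={},
            tile_table=pd.DataFrame(),
            n_tissue_tiles=0,
            n_tumor_tiles=0,
            indeterminate=True,
            provenance=provenance,
        )
        if out_dir is not None:
            _write_outputs(report, slide, None, out_dir, top_k_overlays, config)
        return report

    clf = make_classifier(config)
    pmap = probability_map(slide, grid, clf)
    tumor_tiles = binarize_map(pmap, config.probability_threshold)

    grid512 = enumerate_tiles(mask, config.score_tile_size, config.min_tissue_fraction)
    origins = _scoring_tiles(grid512, pmap, tumor_tiles, config)
    log.info("scoring tiles: %d of %d tissue tiles", len(origins), len(grid512))

    vectors = config.stain_vectors()
    brown = config.brown_range()
    seg = config.segmentation_params()
    rows = []
    features = []
    overlays = []
    for r0, c0 in origins:
        patch = slide.read_region((r0, c0), config.score_tile_size, level=0)
        intensity, dab, labels, cells = measure_patch(
            patch, vectors, brown, seg, ring_width=config.ring_width
        )
        feats = patch_features(cells, intensity, config.completeness_cutoff)
        features.append(feats)
        rows.append(
            {
                "row0": r0,
                "col0": c0,
                "staining_intensity": feats.staining_intensity,
                "positive_cell_ratio": feats.positive_cell_ratio,
                "circumferential_ratio": feats.circumferential_ratio,
                "n_cells": feats.n_cells,
                "n_positive": feats.n_positive,
            }
        )
        overlays.append((feats.n_cells, (r0, c0), patch, dab, labels, cells))
    tile_table = pd.DataFrame(rows)

    try:
        slide_feats = aggregate_slide(features)
    except NoTumorTilesError:
        report = SlideReport(
            ihc_class="indeterminate",
            her2_status="indeterminate",
            ish_reflex=False,
            staining_only=None,
            integrated=None,
            slide_features={},
            tile_table=tile_table,
            n_tissue_tiles=len(grid),
            n_tumor_tiles=0,
            indeterminate=True,
            provenance=provenance,
        )
        if out_dir is not None:
            _write_outputs(report, slide, pmap, out_dir, top_k_overlays, config)
        return report

    table = config.threshold_table()
    staining_score = classify_staining_only(slide_feats, table)
    integrated_score = classify_integrated(slide_feats, table)
    report = SlideReport(
        ihc_class=integrated_score.ihc_class,
        her2_status=integrated_score.her2_status,
        ish_reflex=integrated_score.ish_reflex,
        staining_only=staining_score,
        integrated=integrated_score,
        slide_features={
            "staining_intensity": slide_feats.staining_intensity,
            "positive_cell_ratio": slide_feats.positive_cell_ratio,
            "circumferential_ratio": slide_feats.circumferential_ratio,
            "n_tiles": slide_feats.n_tiles,
            "n_cells": slide_feats.n_cells,
        },
        tile_table=tile_table,
        n_tissue_tiles=len(grid),
        n_tumor_tiles=len(origins),
        provenance=provenance,
    )
    if out_dir is not None:
        _write_outputs(report, slide, pmap, out_dir, top_k_overlays, config, overlays)
    return report


def _heatmap_overlay(slide: Pyramid, pmap, config: PipelineConfig) -> np.ndarray:
    """Blend the tumor-probability map over the slide thumbnail."""
    thumb = slide.levels[-1].astype(float) / 255.0
    vals = np.nan_to_num(pmap.values, nan=0.0) if pmap is not None else None
    if vals is None or vals.size == 0:
        return (thumb * 255).astype(np.uint8)
    cmap = colormaps["jet"]
    heat = cmap(np.clip(vals, 0, 1))[..., :3]
    heat = resize(heat, thumb.shape[:2] + (3,), order=0, anti_aliasing=False)
    alpha = 0.45 * resize(
        (np.isfinite(pmap.values)).astype(float), thumb.shape[:2], order=0
    )
    blended = thumb * (1 - alpha[..., None]) + heat * alpha[..., None]
    return np.clip(blended * 255, 0, 255).astype(np.uint8)


def _cell_overlay(patch, dab, labels, cells, cutoff: float) -> np.ndarray:
    """Color cell boundaries: yellow = DAB-positive, blue = negative."""
    out = np.asarray(patch).copy()
    for cell in cells:
        r0, c0, _, _ = cell.bbox
        boundary = cell.region_mask & ~dilation(~cell.region_mask, disk(1))
        edge = cell.region_mask ^ boundary
        rr, cc = np.nonzero(edge)
        color = (255, 220, 0) if cell.dab_overlap else (40, 60, 200)
        out[rr + r0, cc + c0] = color
    return out


def _write_outputs(
    report: SlideReport,
    slide: Pyramid,
    pmap,
    out_dir,
    top_k: int,
    config: PipelineConfig,
    overlays=None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report.to_json_dict(), indent=1))
    report.tile_table.to_csv(out / "tiles.csv", index=False)
    iio.imwrite(out / "heatmap.png", _heatmap_overlay(slide, pmap, config))
    if overlays:
        ranked = sorted(overlays, key=lambda t: (-t[0], t[1]))[:top_k]
        for n, (r0, c0), patch, dab, labels, cells in ranked:
            img = _cell_overlay(patch, dab, labels, cells, config.completeness_cutoff)
            iio.imwrite(out / f"overlay_{r0}_{c0}.png", img)


def run_eval(
    predictions_csv, truth_csv, out_dir: str | Path | None = None
) -> dict[str, dict]:
    """Compare prediction CSV columns against a truth CSV by ``slide_id``.

    Every non-ID column of the predictions file is scored with a confusion
    matrix and overall accuracy against the truth file's ``ihc_class``.
    """
    pred = pd.read_csv(predictions_csv)
    truth = pd.read_csv(truth_csv)
    if pred.empty or truth.empty:
        raise InvalidInputError("empty predictions or truth CSV")
    if "slide_id" not in pred.columns or "slide_id" not in truth.columns:
        raise InvalidInputError("both CSVs need a slide_id column")
    merged = pred.merge(truth[["slide_id", "ihc_class"]], on="slide_id", how="inner")
    if len(merged) != len(pred) or len(merged) != len(truth):
        raise InvalidInputError("slide_id mismatch between predictions and truth")
    classes = ["0", "1+", "2+", "3+"]
    results: dict[str, dict] = {}
    for col in pred.columns:
        if col == "slide_id":
            continue
        cm = evaluation.confusion_matrix(
            merged["ihc_class"].astype(str), merged[col].astype(str), classes
        )
        acc = evaluation.overall_accuracy(cm)
        results[col] = {"confusion": cm, "accuracy": acc}
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            cm.to_csv(out / f"confusion_{col}.csv")
    if out_dir is not None:
        summary = {k: {"accuracy": v["accuracy"]} for k, v in results.items()}
        (Path(out_dir) / "metrics.json").write_text(json.dumps(summary, indent=1))
    return results
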