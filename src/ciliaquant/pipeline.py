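"""End-to-end orchestration: simulate -> measure -> score.

The measurement stage mirrors the classic per-image flow of object-based
two-channel analysis: segment the test and marker channels independently,
measure object shape/intensity features, compute image-level colocalization,
relate red objects to green objects by overlap, and record centroid
distances.  Failures are isolated per image and summarized at the end, so a
single corrupt file never aborts a study.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import scoring
from .colocalization import ColocConfig, coloc_image
from .features import measure_objects
from .io import SlideRecord, discover_slides, write_table
from .pairing import centroid_distance, relate_objects
from .segmentation import SegmentationConfig, segment_channel
from .vocab import DEFAULT_PIXEL_SIZE_UM, DEFAULT_ROLE_TO_COLOR

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "donor", "condition", "antibody", "image_id", "object_id", "channel",
    "AreaShape_Area", "AreaShape_Area_um2", "AreaShape_Eccentricity",
    "AreaShape_Compactness", "Intensity_MassDisplacement",
    "Intensity_MeanIntensity", "Intensity_IntegratedIntensity",
    "Location_Center_Y", "Location_Center_X",
]
PAIR_COLUMNS = [
    "donor", "condition", "antibody", "image_id", "red_id", "green_id",
    "overlap_px", "distance_px", "distance_um", "green_multiplicity",
]
COLOC_COLUMNS = [
    "donor", "condition", "antibody", "image_id",
    "Correlation_RWC_RED_GREEN", "Correlation_RWC_GREEN_RED",
    "Correlation_Pearson", "threshold_red", "threshold_green",
    "n_coloc_pixels", "n_mask_pixels",
]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, loadable from one YAML file."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    role_to_color: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ROLE_TO_COLOR))
    segmentation_test: SegmentationConfig = field(default_factory=SegmentationConfig)
    segmentation_marker: SegmentationConfig = field(default_factory=SegmentationConfig)
    coloc: ColocConfig = field(default_factory=ColocConfig)
    alpha: float = 0.001
    directions: dict[str, str] = field(
        default_factory=lambda: dict(scoring.DEFAULT_DIRECTIONS))
    exclude_conditions: list[str] = field(default_factory=list)
    unique_pairs_only: bool = True

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        for role in ("test", "marker"):
            if role not in self.role_to_color:
                raise ValueError(f"role_to_color missing role {role!r}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for parameter, d in self.directions.items():
            if d not in ("lower", "higher"):
                raise ValueError(
                    f"direction for {parameter!r} must be 'lower' or 'higher'")

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key, sub_cls in (("segmentation_test", SegmentationConfig),
                             ("segmentation_marker", SegmentationConfig),
                             ("coloc", ColocConfig)):
            if key in raw and isinstance(raw[key], Mapping):
                raw[key] = sub_cls(**raw[key])
        return cls(**raw)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(raw)


def measure_image_pair(
    red, green,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[list[dict], list[dict], dict]:
    """Measure one field of view given its test (red) and marker (green)
    channel images; returns (feature rows, pair rows, coloc row) without the
    slide metadata columns."""
    seg_red = segment_channel(red, cfg.segmentation_test)
    seg_green = segment_channel(green, cfg.segmentation_marker)
    feats_red = measure_objects(seg_red, red, cfg.pixel_size_um)
    feats_green = measure_objects(seg_green, green, cfg.pixel_size_um)

    feature_rows = []
    for channel, feats in (("test", feats_red), ("marker", feats_green)):
        for f in feats:
            feature_rows.append({
                "object_id": f.object_id, "channel": channel,
                "AreaShape_Area": f.area_px, "AreaShape_Area_um2": f.area_um2,
                "AreaShape_Eccentricity": f.eccentricity,
                "AreaShape_Compactness": f.compactness,
                "Intensity_MassDisplacement": f.mass_displacement_px,
                "Intensity_MeanIntensity": f.mean_intensity,
                "Intensity_IntegratedIntensity": f.integrated_intensity,
                "Location_Center_Y": f.centroid[0],
                "Location_Center_X": f.centroid[1],
            })

    red_by_id = {f.object_id: f for f in feats_red}
    green_by_id = {f.object_id: f for f in feats_green}
    pair_rows = []
    for pair in relate_objects(seg_red, seg_green):
        pair = centroid_distance(pair, red_by_id, green_by_id, cfg.pixel_size_um)
        pair_rows.append({
            "red_id": pair.red_id, "green_id": pair.green_id,
            "overlap_px": pair.overlap_px, "distance_px": pair.distance_px,
            "distance_um": pair.distance_um,
            "green_multiplicity": pair.green_multiplicity,
        })

    res = coloc_image(red, green, cfg.coloc)
    coloc_row = {
        "Correlation_RWC_RED_GREEN": res.rwc_red_green,
        "Correlation_RWC_GREEN_RED": res.rwc_green_red,
        "Correlation_Pearson": res.pearson,
        "threshold_red": res.threshold_red,
        "threshold_green": res.threshold_green,
        "n_coloc_pixels": res.n_coloc_pixels,
        "n_mask_pixels": res.n_mask_pixels,
    }
    return feature_rows, pair_rows, coloc_row


def measure_slides(
    slides: list[SlideRecord],
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Run the measurement stage over discovered slides.

    Returns (features, pairs, coloc, errors); per-image failures are caught,
    logged, and listed in ``errors`` without stopping the study.
    """
    feature_rows: list[dict] = []
    pair_rows: list[dict] = []
    coloc_rows: list[dict] = []
    errors: list[str] = []
    for slide in slides:
        meta = {"donor": slide.donor, "condition": slide.condition,
                "antibody": slide.antibody}
        logger.info("measuring slide %s/%s/%s (%d images)",
                    slide.donor, slide.condition, slide.antibody, len(slide.images))
        for image_set in slide.images:
            try:
                red = image_set.channel("test", cfg.role_to_color, cfg.pixel_size_um)
                green = image_set.channel("marker", cfg.role_to_color,
                                          cfg.pixel_size_um)
                f_rows, p_rows, c_row = measure_image_pair(red, green, cfg)
            except Exception as exc:  # noqa: BLE001 — fault isolation per image
                msg = (f"{slide.donor}/{slide.condition}/{slide.antibody}/"
                       f"{image_set.image_id}: {exc}")
                logger.error("image failed: %s", msg)
                errors.append(msg)
                continue
            tag = {**meta, "image_id": image_set.image_id}
            feature_rows += [{**tag, **r} for r in f_rows]
            pair_rows += [{**tag, **r} for r in p_rows]
            coloc_rows.append({**tag, **c_row})
    features = pd.DataFrame(feature_rows, columns=FEATURE_COLUMNS)
    pairs = pd.DataFrame(pair_rows, columns=PAIR_COLUMNS)
    coloc = pd.DataFrame(coloc_rows, columns=COLOC_COLUMNS)
    return features, pairs, coloc, errors


def measure_study(
    root: str | Path,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Discover slides under ``root``, measure them, optionally write the
    three CSVs (features.csv, pairs.csv, coloc.csv) to ``out_dir``."""
    slides, warnings = discover_slides(root, cfg.role_to_color)
    if not slides:
        raise FileNotFoundError(
            f"no complete slides found under {root}"
            + (f" ({len(warnings)} validation warning(s))" if warnings else ""))
    features, pairs, coloc, errors = measure_slides(slides, cfg)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(features, out_dir / "features.csv", FEATURE_COLUMNS)
        write_table(pairs, out_dir / "pairs.csv", PAIR_COLUMNS)
        write_table(coloc, out_dir / "coloc.csv", COLOC_COLUMNS)
        if errors:
            (out_dir / "errors.txt").write_text("\n".join(errors) + "\n")
    return features, pairs, coloc, errors


def score_study(
    features: pd.DataFrame,
    pairs: pd.DataFrame,
    coloc: pd.DataFrame,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Aggregate, screen and rank one measured study.

    Returns a dict with the slide table, screen results and (where at least
    two entities exist) condition/antibody rank matrices; writes the report
    CSVs when ``out_dir`` is given.
    """
    slide_table = scoring.aggregate(features, pairs, coloc,
                                    unique_only=cfg.unique_pairs_only)
    if slide_table.empty:
        raise ValueError("no measurements survived aggregation; nothing to score")
    significant, pvals = scoring.screen_parameters(slide_table, alpha=cfg.alpha)
    result: dict[str, Any] = {
        "slide_table": slide_table,
        "significant": significant,
        "p_values": pvals,
    }
    subset = None
    if cfg.exclude_conditions:
        keep = [c for c in slide_table["condition"].unique()
                if c not in cfg.exclude_conditions]
        subset = keep
    for axis in ("condition", "antibody"):
        if slide_table[axis].nunique() >= 2:
            rm = scoring.rank_entities(slide_table, cfg.directions, axis=axis)
            result[f"ranks_{axis}"] = rm
            result[f"overall_{axis}"] = rm.overall()
        else:
            logger.warning("only one %s present: ranking skipped", axis)
    if subset is not None and slide_table["antibody"].nunique() >= 2:
        rm = scoring.rank_entities(slide_table, cfg.directions, axis="antibody",
                                   condition_subset=subset)
        result["ranks_antibody_subset"] = rm
        result["overall_antibody_subset"] = rm.overall()
    if out_dir is not None:
        scoring.performance_report(slide_table, out_dir, cfg.directions,
                                   alpha=cfg.alpha, condition_subset=subset)
    return result
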