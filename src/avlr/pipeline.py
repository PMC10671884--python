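"""End-to-end orchestration: disc -> rings -> skeleton -> metrics -> ratios.

The stages are importable individually; this module wires them into the
batch workflow the command line exposes, with per-image failure isolation
so one unreadable raster does not abort a screening run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import features, io, roi, skeleton
from .features import ImageFeatureRecord
from .io import FeatureTables, Palette, VesselLabelMap
from .optic_disc import DiscNotFoundError, OpticDisc, localize_od, manual_od

log = logging.getLogger("avlr")


@dataclasses.dataclass
class PipelineConfig:
    """All tunables of the batch pipeline, loadable from a YAML file."""

    palette: Palette = dataclasses.field(default_factory=Palette)
    ring_factors: tuple[tuple[float, float], ...] = ((2.0, 3.0), (2.0, 5.0))
    od_override: tuple[float, float, float] | None = None  # (row, col, radius)
    brightness_quantile: float = 0.995
    od_min_area: int = 200
    min_spur: float = 10.0
    max_junction_len: float = 5.0
    smoothing_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_spur < 0 or self.max_junction_len < 0:
            raise ValueError("thresholds must be >= 0")
        for a, b in self.ring_factors:
            if not 0 <= a < b:
                raise ValueError(f"invalid ring factors ({a}, {b})")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        cfg = io.load_config(path)
        kwargs: dict = {}
        if "palette" in cfg or "palette_tolerance" in cfg:
            kwargs["palette"] = io.palette_from_config(cfg)
        if "ring_factors" in cfg:
            kwargs["ring_factors"] = tuple(tuple(map(float, p)) for p in cfg["ring_factors"])
        if "od_override" in cfg and cfg["od_override"]:
            kwargs["od_override"] = tuple(map(float, cfg["od_override"]))
        for key in ("brightness_quantile", "min_spur", "max_junction_len"):
            if key in cfg:
                kwargs[key] = float(cfg[key])
        for key in ("od_min_area", "smoothing_window", "seed"):
            if key in cfg:
                kwargs[key] = int(cfg[key])
        return cls(**kwargs)

    def provenance(self) -> dict:
        return {
            "palette": {str(k): io.CLASS_NAMES[v] for k, v in self.palette.colors.items()},
            "palette_tolerance": self.palette.tolerance,
            "ring_factors": [list(p) for p in self.ring_factors],
            "od_override": list(self.od_override) if self.od_override else None,
            "brightness_quantile": self.brightness_quantile,
            "od_min_area": self.od_min_area,
            "min_spur": self.min_spur,
            "max_junction_len": self.max_junction_len,
            "smoothing_window": self.smoothing_window,
            "seed": self.seed,
        }


def analyze_labels(labels: VesselLabelMap, image_id: str, eye: str = "unknown",
                   roi_name: str = "full", config: PipelineConfig | None = None,
                   ) -> tuple[pd.DataFrame, ImageFeatureRecord]:
    """Skeletonize a (possibly ring-clipped) label map and aggregate ratios."""
    config = config or PipelineConfig()
    segs = skeleton.segments_from_labels(
        labels, roi_name=roi_name, min_spur=config.min_spur,
        max_junction_len=config.max_junction_len)
    return features.analyze_segments(segs, image_id, eye=eye, roi_name=roi_name,
                                     window=config.smoothing_window)


def analyze_image(image: io.FundusImage, labels: VesselLabelMap,
                  config: PipelineConfig | None = None,
                  ) -> tuple[list[pd.DataFrame], list[ImageFeatureRecord], OpticDisc]:
    """Run every configured ring ROI of one image."""
    config = config or PipelineConfig()
    if config.od_override is not None:
        disc = manual_od(config.od_override[:2], config.od_override[2])
    else:
        disc = localize_od(image, brightness_quantile=config.brightness_quantile,
                           min_area=config.od_min_area)
    seg_frames, records = [], []
    for inner, outer in config.ring_factors:
        ring = roi.RingROI(disc, inner, outer)
        clipped = roi.clip_labels(labels, ring)
        seg_df, rec = analyze_labels(clipped, image.image_id, eye=image.eye,
                                     roi_name=ring.name, config=config)
        seg_frames.append(seg_df)
        records.append(rec)
    return seg_frames, records, disc


def run(image_paths: list[str], label_paths: list[str],
        config: PipelineConfig | None = None,
        out_dir: str | Path = "avlr_out",
        eyes: list[str] | None = None) -> tuple[FeatureTables, int]:
    """Batch pipeline over matched image/label lists.

    Writes ``segments.csv``, ``images.csv`` and ``provenance.json`` to
    ``out_dir``.  Per-image failures are logged and skipped; the returned
    integer is the number of failed images (also suitable as exit status).
    """
    config = config or PipelineConfig()
    if len(image_paths) != len(label_paths):
        raise ValueError("image and label lists must be matched 1:1")
    eyes = eyes or ["unknown"] * len(image_paths)
    seg_frames: list[pd.DataFrame] = []
    records: list[ImageFeatureRecord] = []
    n_failed = 0
    for img_path, lab_path, eye in zip(image_paths, label_paths, eyes):
        try:
            image = io.read_fundus_image(img_path, eye=eye)
            labels = io.read_label_map(lab_path, config.palette)
            if labels.shape != (image.height, image.width):
                raise ValueError("label raster shape differs from image")
            frames, recs, disc = analyze_image(image, labels, config)
            seg_frames.extend(frames)
            records.extend(recs)
            for rec in recs:
                log.info("%s %s: %d artery / %d vein segments (OD r=%.1f)",
                         rec.image_id, rec.roi_name, rec.n_artery_segments,
                         rec.n_vein_segments, disc.radius)
        except (OSError, ValueError, DiscNotFoundError) as exc:
            log.error("image %s failed: %s", img_path, exc)
            n_failed += 1
    tables = features.build_feature_tables(seg_frames, records)
    out = Path(out_dir)
    io.write_feature_tables(tables, out)
    (out / "provenance.json").write_text(json.dumps(config.provenance(), indent=2))
    return tables, n_failed
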