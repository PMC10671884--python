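"""Image-level arteriovenous length ratios and feature tables.

Each of the nine segment metrics is averaged (unweighted) over the usable
artery segments and over the usable vein segments of an image/ROI; the
AVLR for that metric is ``artery mean / vein mean``.  A ratio near 1 means
arteries and veins have similar length/tortuosity in that retina; marked
deviation in either direction flags asymmetric elongation.

Segments of unknown class (crossings, ties) and too-short segments are
excluded from all means.  If either class contributes no usable segment
the ratios are flagged missing rather than NaN-propagated, because small
2-3 ROD rings can legitimately lack one class.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import (ARTERY, CLASS_NAMES, METRIC_NAMES, SEGMENT_COLUMNS, VEIN,
                 FeatureTables)
from .metrics import SegmentMetrics, metrics_for_segment
from .skeleton import VesselSegment

RATIO_NAMES = [f"avlr_{m}" for m in METRIC_NAMES]


@dataclasses.dataclass
class ImageFeatureRecord:
    """Nine AVLR ratios plus per-class summary statistics for one image/ROI."""

    image_id: str
    eye: str
    roi_name: str
    n_artery_segments: int
    n_vein_segments: int
    ratios: dict[str, float]            # avlr_<metric> -> value (NaN if missing)
    stats: dict[str, float]             # <class>_<metric>_<stat> -> value
    incomplete: bool = False            # one class had zero usable segments

    def as_row(self) -> dict[str, float | str | int | bool]:
        row: dict = {
            "image_id": self.image_id,
            "eye": self.eye,
            "roi_name": self.roi_name,
            "n_artery_segments": self.n_artery_segments,
            "n_vein_segments": self.n_vein_segments,
            "incomplete": self.incomplete,
        }
        row.update(self.ratios)
        row.update(self.stats)
        return row


def segment_table(segments: list[VesselSegment],
                  metrics: list[SegmentMetrics],
                  image_id: str, eye: str = "unknown",
                  roi_name: str = "") -> pd.DataFrame:
    """One row per segment, in the documented ``segments.csv`` column order."""
    rows = []
    for seg, sm in zip(segments, metrics):
        row = {
            "image_id": image_id,
            "eye": eye,
            "roi_name": roi_name or seg.roi_name,
            "segment_id": seg.segment_id,
            "vessel_class": CLASS_NAMES[seg.vessel_class],
            "end_type_a": seg.end_types[0],
            "end_type_b": seg.end_types[1],
            "n_pixels": seg.n_pixels,
            "too_short": sm.too_short,
            "n_inflections": sm.n_inflections,
        }
        row.update(sm.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _usable(seg_df: pd.DataFrame) -> pd.DataFrame:
    return seg_df[seg_df["vessel_class"].isin(["artery", "vein"])
                  & ~seg_df["too_short"].astype(bool)]


def image_ratios(seg_df: pd.DataFrame, image_id: str | None = None,
                 eye: str = "unknown", roi_name: str | None = None) -> ImageFeatureRecord:
    """Aggregate a segment table into the nine AVLR ratios and class stats.

    ``seg_df`` is a :func:`segment_table` frame (possibly empty).  Ratios
    are artery-mean over vein-mean per metric; a metric whose vein mean is
    zero (e.g. perfectly straight veins give zero SOAM) yields NaN for that
    ratio only.
    """
    if image_id is None:
        image_id = str(seg_df["image_id"].iloc[0]) if len(seg_df) else ""
    if roi_name is None:
        roi_name = str(seg_df["roi_name"].iloc[0]) if len(seg_df) else ""
    if len(seg_df) and eye == "unknown":
        eye = str(seg_df["eye"].iloc[0])
    use = _usable(seg_df)
    art = use[use["vessel_class"] == "artery"]
    vein = use[use["vessel_class"] == "vein"]
    incomplete = len(art) == 0 or len(vein) == 0
    ratios: dict[str, float] = {}
    stats: dict[str, float] = {}
    for m in METRIC_NAMES:
        a_vals = art[m].to_numpy(dtype=float)
        v_vals = vein[m].to_numpy(dtype=float)
        a_vals = a_vals[np.isfinite(a_vals)]
        v_vals = v_vals[np.isfinite(v_vals)]
        if incomplete or len(a_vals) == 0 or len(v_vals) == 0 or v_vals.mean() == 0:
            ratios[f"avlr_{m}"] = float("nan")
        else:
            ratios[f"avlr_{m}"] = float(a_vals.mean() / v_vals.mean())
        for cls, vals in (("artery", a_vals), ("vein", v_vals)):
            prefix = f"{cls}_{m}"
            stats[f"{prefix}_count"] = float(len(vals))
            if len(vals):
                stats[f"{prefix}_mean"] = float(vals.mean())
                stats[f"{prefix}_std"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
                stats[f"{prefix}_min"] = float(vals.min())
                stats[f"{prefix}_max"] = float(vals.max())
                stats[f"{prefix}_median"] = float(np.median(vals))
            else:
                for s in ("mean", "std", "min", "max", "median"):
                    stats[f"{prefix}_{s}"] = float("nan")
    return ImageFeatureRecord(
        image_id=image_id, eye=eye, roi_name=roi_name,
        n_artery_segments=int(len(art)), n_vein_segments=int(len(vein)),
        ratios=ratios, stats=stats, incomplete=incomplete,
    )


def segmentwise_ratios(seg_df: pd.DataFrame) -> pd.DataFrame:
    """Per-segment ratios: each metric over the opposite-class image mean.

    The mean of the artery rows of column ``ratio_<m>`` equals the image
    level ``avlr_<m>`` by construction (and symmetrically for veins).
    Rows are flagged missing when no opposite-class segment exists.
    """
    use = _usable(seg_df)
    means: dict[str, dict[str, float]] = {}
    for cls in ("artery", "vein"):
        sub = use[use["vessel_class"] == cls]
        means[cls] = {}
        for m in METRIC_NAMES:
            vals = sub[m].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            means[cls][m] = float(vals.mean()) if len(vals) else float("nan")
    out = use.copy()
    opposite = {"artery": "vein", "vein": "artery"}
    for m in METRIC_NAMES:
        denom = out["vessel_class"].map(lambda c: means[opposite[c]][m])
        out[f"ratio_{m}"] = out[m] / denom
    out["missing_opposite"] = out["vessel_class"].map(
        lambda c: not np.isfinite(means[opposite[c]]["chord"]))
    return out


def analyze_segments(segments: list[VesselSegment], image_id: str,
                     eye: str = "unknown", roi_name: str = "",
                     window: int = 5) -> tuple[pd.DataFrame, ImageFeatureRecord]:
    """Metrics + aggregation for a list of extracted segments."""
    sms = [metrics_for_segment(s, window=window) for s in segments]
    seg_df = segment_table(segments, sms, image_id, eye=eye, roi_name=roi_name)
    rec = image_ratios(seg_df, image_id=image_id, eye=eye, roi_name=roi_name)
    return seg_df, rec


def build_feature_tables(seg_frames: list[pd.DataFrame],
                         records: list[ImageFeatureRecord]) -> FeatureTables:
    seg = (pd.concat(seg_frames, ignore_index=True)
           if seg_frames else pd.DataFrame(columns=SEGMENT_COLUMNS))
    img = pd.DataFrame([r.as_row() for r in records])
    if img.empty:
        img = pd.DataFrame(columns=["image_id", "eye", "roi_name",
                                    "n_artery_segments", "n_vein_segments",
                                    "incomplete", *RATIO_NAMES])
    return FeatureTables(segment_rows=seg, image_rows=img)
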