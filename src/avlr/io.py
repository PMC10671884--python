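"""Raster and table I/O for the AVLR pipeline.

Conventions used throughout the package:

* Coordinates are 0-based ``(row, col)``; row increases downward.
* Vessel classes are small integer codes (:data:`BACKGROUND`,
  :data:`ARTERY`, :data:`VEIN`, :data:`UNKNOWN`).
* Label rasters are color-coded RGB images decoded through a
  :class:`Palette`; the palette is configuration because artery/vein
  label color conventions differ between datasets.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from PIL import Image

# vessel class codes
BACKGROUND = 0
ARTERY = 1
VEIN = 2
UNKNOWN = 3

CLASS_NAMES = {BACKGROUND: "background", ARTERY: "artery", VEIN: "vein", UNKNOWN: "unknown"}
NAME_TO_CLASS = {v: k for k, v in CLASS_NAMES.items()}

#: column order of the per-segment CSV (``segments.csv``)
SEGMENT_COLUMNS = [
    "image_id", "eye", "roi_name", "segment_id", "vessel_class",
    "end_type_a", "end_type_b", "n_pixels", "too_short",
    "chord", "arc", "dm", "icm", "icmb", "soam", "nc", "sdac", "cl",
    "n_inflections",
]

METRIC_NAMES = ["chord", "arc", "dm", "icm", "icmb", "soam", "nc", "sdac", "cl"]
STAT_NAMES = ["count", "mean", "std", "min", "max", "median"]


class ConfigurationError(ValueError):
    """Raised when a palette or config file cannot support the requested input."""


@dataclasses.dataclass
class FundusImage:
    """An RGB fundus photograph plus identifying metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    image_id: str = ""
    eye: str = "unknown"  # left / right / unknown

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("FundusImage expects an (H, W, 3) RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if self.eye not in ("left", "right", "unknown"):
            raise ValueError(f"eye must be left/right/unknown, got {self.eye!r}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class VesselLabelMap:
    """Per-pixel artery/vein class raster aligned with a fundus image."""

    classes: np.ndarray  # (H, W) uint8 over the class codes
    provenance: str = "file"  # file / synthetic

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.ndim != 2:
            raise ValueError("label map must be 2-D")
        bad = ~np.isin(self.classes, (BACKGROUND, ARTERY, VEIN, UNKNOWN))
        if bad.any():
            raise ValueError("label map contains codes outside the class set")

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape

    def counts(self) -> dict[str, int]:
        return {name: int((self.classes == code).sum()) for code, name in CLASS_NAMES.items()}


@dataclasses.dataclass
class Palette:
    """Mapping from label-raster RGB colors to vessel classes.

    ``tolerance`` is a per-channel slack (Chebyshev radius) so that
    anti-aliased label rasters still decode; a pixel is assigned the class
    of the nearest palette color whose per-channel distance is within
    tolerance, otherwise ``fallback``.
    """

    colors: Mapping[tuple[int, int, int], int] = dataclasses.field(
        default_factory=lambda: {
            (0, 0, 0): BACKGROUND,
            (255, 0, 0): ARTERY,
            (0, 0, 255): VEIN,
        }
    )
    tolerance: int = 30
    fallback: int = UNKNOWN

    def __post_init__(self) -> None:
        seen: dict[tuple[int, int, int], int] = {}
        for rgb, cls in self.colors.items():
            if rgb in seen and seen[rgb] != cls:
                raise ConfigurationError(f"color {rgb} claimed by two classes")
            seen[rgb] = cls

    def classify(self, rgb: np.ndarray) -> np.ndarray:
        """Vectorized nearest-palette-color classification.

        Parameters
        ----------
        rgb : (H, W, 3) uint8 array.

        Returns
        -------
        (H, W) uint8 class raster.
        """
        rgb = np.asarray(rgb, dtype=np.int16)
        h, w, _ = rgb.shape
        entries = list(self.colors.items())
        pal = np.array([c for c, _ in entries], dtype=np.int16)  # (K, 3)
        cls = np.array([k for _, k in entries], dtype=np.uint8)
        # per-pixel Chebyshev distance to each palette entry
        diff = np.abs(rgb[:, :, None, :] - pal[None, None, :, :]).max(axis=3)  # (H, W, K)
        nearest = diff.argmin(axis=2)
        within = np.take_along_axis(diff, nearest[:, :, None], axis=2)[:, :, 0] <= self.tolerance
        out = np.where(within, cls[nearest], np.uint8(self.fallback))
        return out.astype(np.uint8)


def read_fundus_image(path: str | os.PathLike, image_id: str | None = None,
                      eye: str = "unknown") -> FundusImage:
    """Read a PNG/TIFF fundus raster as RGB."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"))
    return FundusImage(arr, image_id=image_id or Path(path).stem, eye=eye)


def read_label_map(path: str | os.PathLike, palette: Palette | None = None) -> VesselLabelMap:
    """Decode a color-coded artery/vein label raster through a palette.

    Grayscale rasters are accepted only if the palette maps gray colors
    (r == g == b); otherwise a :class:`ConfigurationError` names the problem.
    """
    palette = palette or Palette()
    try:
        with Image.open(path) as im:
            mode = im.mode
            arr = np.asarray(im.convert("RGB"))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read label raster {path}: {exc}") from exc
    if mode in ("L", "I", "I;16", "1"):
        grays = [c for c in palette.colors if c[0] == c[1] == c[2]]
        if not grays:
            raise ConfigurationError(
                f"{path} is grayscale but the palette defines no gray colors; "
                "add gray palette entries (r==g==b) for each class"
            )
    return VesselLabelMap(palette.classify(arr), provenance="file")


@dataclasses.dataclass
class FeatureTables:
    """The two output tables: one row per segment, one per (image, ROI)."""

    segment_rows: pd.DataFrame
    image_rows: pd.DataFrame

    def validate(self) -> None:
        if len(self.segment_rows):
            seg_ids = set(self.segment_rows["image_id"])
            img_ids = set(self.image_rows["image_id"])
            missing = seg_ids - img_ids
            if missing:
                raise ValueError(f"segment rows reference absent images: {sorted(missing)}")


def write_feature_tables(tables: FeatureTables, out_dir: str | os.PathLike) -> tuple[Path, Path]:
    """Write ``segments.csv`` and ``images.csv`` with 12 significant digits.

    Re-reading the files reproduces every numeric value at the serialized
    precision, which is enough for bit-equal float round-trips in practice.
    """
    tables.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seg_path = out / "segments.csv"
    img_path = out / "images.csv"
    tables.segment_rows.to_csv(seg_path, index=False, float_format="%.12g")
    tables.image_rows.to_csv(img_path, index=False, float_format="%.12g")
    return seg_path, img_path


def read_feature_tables(out_dir: str | os.PathLike) -> FeatureTables:
    out = Path(out_dir)
    return FeatureTables(
        segment_rows=pd.read_csv(out / "segments.csv"),
        image_rows=pd.read_csv(out / "images.csv"),
    )


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML key-value config file (palette, thresholds, OD override)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path} must contain a key-value mapping")
    return cfg


def palette_from_config(cfg: dict) -> Palette:
    """Build a Palette from a config mapping.

    Expected form::

        palette:
          artery: [255, 0, 0]
          vein: [0, 0, 255]
          background: [0, 0, 0]
        palette_tolerance: 30
        palette_fallback: unknown
    """
    spec = cfg.get("palette")
    if not spec:
        return Palette(tolerance=int(cfg.get("palette_tolerance", 30)))
    colors: dict[tuple[int, int, int], int] = {}
    for name, rgb in spec.items():
        if name not in NAME_TO_CLASS:
            raise ConfigurationError(f"unknown vessel class {name!r} in palette")
        colors[tuple(int(v) for v in rgb)] = NAME_TO_CLASS[name]
    fallback = NAME_TO_CLASS[cfg.get("palette_fallback", "unknown")]
    return Palette(colors=colors, tolerance=int(cfg.get("palette_tolerance", 30)),
                   fallback=fallback)
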