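"""Seeded synthetic fundus phantoms with exact morphometric ground truth.

A phantom scene is a bright circular "optic disc" on a dark background plus
artery/vein trees drawn as parametric curves (lines, circular arcs, sines,
cubic Beziers).  For every curve the generator computes chord length, arc
length (dense numeric integration), interior inflection count, total
turning angle and mean absolute curvature directly from the parametric
form — never through the raster pipeline — so the phantoms double as
independent oracles for every pipeline stage.

Rendering is deterministic for a fixed seed; anti-aliasing is off so
palette decoding of the label raster is exact (an anti-aliased mode
exercises palette tolerance instead).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np

from .io import ARTERY, BACKGROUND, UNKNOWN, VEIN, FundusImage, VesselLabelMap

#: rendering colors: (fundus RGB, label RGB)
_VESSEL_COLOR = {ARTERY: ((150, 40, 40), (255, 0, 0)),
                 VEIN: ((50, 40, 120), (0, 0, 255))}
_DISC_VALUE = 235
_BACKGROUND_VALUE = 20
_TRUTH_SAMPLES = 10_000


@dataclasses.dataclass
class CurveSpec:
    """Parametric centerline of one synthetic vessel.

    ``params`` per kind:

    * ``line``: ``p0``, ``p1`` (row, col)
    * ``circular_arc``: ``center``, ``radius``, ``theta0``, ``theta1`` (rad)
    * ``sine``: ``start``, ``angle`` (direction, rad), ``length`` (along the
      axis), ``amplitude``, ``wavelength``
    * ``cubic_bezier``: ``control`` — four (row, col) points
    """

    kind: str
    params: dict
    width: int = 3
    vessel_class: int = ARTERY

    def __post_init__(self) -> None:
        if self.kind not in ("line", "circular_arc", "sine", "cubic_bezier"):
            raise ValueError(f"unknown curve kind {self.kind!r}")
        if self.width < 1:
            raise ValueError("width must be >= 1")

    def point_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        """Return p(t) for t in [0, 1] as an (N, 2) evaluator."""
        p = self.params
        if self.kind == "line":
            p0 = np.asarray(p["p0"], float)
            p1 = np.asarray(p["p1"], float)
            return lambda t: p0 + np.outer(t, p1 - p0)
        if self.kind == "circular_arc":
            c = np.asarray(p["center"], float)
            r = float(p["radius"])
            t0, t1 = float(p["theta0"]), float(p["theta1"])

            def arc(t: np.ndarray) -> np.ndarray:
                th = t0 + t * (t1 - t0)
                return c + r * np.column_stack([np.sin(th), np.cos(th)])
            return arc
        if self.kind == "sine":
            start = np.asarray(p["start"], float)
            ang = float(p["angle"])
            length = float(p["length"])
            amp = float(p["amplitude"])
            wav = float(p["wavelength"])
            u = np.array([math.sin(ang), math.cos(ang)])
            n = np.array([-u[1], u[0]])

            def sine(t: np.ndarray) -> np.ndarray:
                x = t * length
                y = amp * np.sin(2 * np.pi * x / wav)
                return start + np.outer(x, u) + np.outer(y, n)
            return sine
        ctrl = np.asarray(p["control"], float)  # (4, 2)

        def bezier(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t)[:, None]
            return ((1 - t) ** 3 * ctrl[0] + 3 * (1 - t) ** 2 * t * ctrl[1]
                    + 3 * (1 - t) * t ** 2 * ctrl[2] + t ** 3 * ctrl[3])
        return bezier

    def sample(self, n: int) -> np.ndarray:
        return self.point_fn()(np.linspace(0.0, 1.0, n))


@dataclasses.dataclass
class CurveTruth:
    """Analytic/numeric ground truth for one curve (pipeline-independent)."""

    chord: float
    arc: float
    n_inflections: int
    total_turning: float   # radians
    mean_abs_curvature: float  # 1/px
    vessel_class: int


@dataclasses.dataclass
class PhantomTruth:
    curves: list[CurveTruth]
    disc_center: tuple[float, float] | None
    disc_radius: float | None


def curve_truth(curve: CurveSpec, n_samples: int = _TRUTH_SAMPLES) -> CurveTruth:
    """Ground-truth morphometry by dense sampling of the parametric form."""
    pts = curve.sample(n_samples)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    diffs = np.diff(pts, axis=0)
    steps = np.linalg.norm(diffs, axis=1)
    arc = float(steps.sum())
    theta = np.unwrap(np.arctan2(diffs[:, 0], diffs[:, 1]))
    dtheta = np.diff(theta)
    total_turning = float(np.abs(dtheta).sum())
    mean_abs_curv = total_turning / arc if arc > 0 else 0.0
    # interior inflections: sign alternations of the turning direction,
    # with near-zero turning (below 1e-7 of the peak) treated as straight
    thresh = max(1e-15, 1e-7 * float(np.abs(dtheta).max(initial=0.0)))
    signs = np.sign(dtheta[np.abs(dtheta) > thresh])
    if len(signs):
        signs = signs[np.concatenate([[True], np.diff(signs) != 0])]
    n_infl = max(0, len(signs) - 1)
    return CurveTruth(chord=chord, arc=arc, n_inflections=n_infl,
                      total_turning=total_turning,
                      mean_abs_curvature=mean_abs_curv,
                      vessel_class=curve.vessel_class)


def _stamp(mask: np.ndarray, pts: np.ndarray, width: int) -> None:
    """Rasterize a dense point chain at the given stroke width (no AA)."""
    h, w = mask.shape
    rows = np.clip(np.rint(pts[:, 0]).astype(int), 0, h - 1)
    cols = np.clip(np.rint(pts[:, 1]).astype(int), 0, w - 1)
    if width <= 1:
        mask[rows, cols] = True
        return
    r = width / 2.0
    rad = int(math.ceil(r))
    dr, dc = np.mgrid[-rad:rad + 1, -rad:rad + 1]
    stencil = np.argwhere(dr ** 2 + dc ** 2 <= r ** 2) - rad
    pix = np.unique(np.column_stack([rows, cols]), axis=0)
    all_pix = pix[:, None, :] + stencil[None, :, :]
    all_pix = all_pix.reshape(-1, 2)
    ok = ((all_pix[:, 0] >= 0) & (all_pix[:, 0] < h)
          & (all_pix[:, 1] >= 0) & (all_pix[:, 1] < w))
    all_pix = all_pix[ok]
    mask[all_pix[:, 0], all_pix[:, 1]] = True


def render_phantom(curves: list[CurveSpec],
                   canvas: tuple[int, int] = (640, 640),
                   disc_center: tuple[float, float] | None = None,
                   disc_radius: float | None = None,
                   seed: int = 0,
                   noise_sigma: float = 0.0,
                   mark_crossings: bool = True,
                   image_id: str = "phantom",
                   eye: str = "unknown",
                   ) -> tuple[FundusImage, VesselLabelMap, PhantomTruth]:
    """Rasterize a phantom scene and compute its ground truth.

    Curves that leave the canvas (including their stroke width) raise a
    ``ValueError``.  Where artery and vein strokes overlap the label pixel
    becomes ``unknown`` when ``mark_crossings`` (crossings belong to
    neither class); the fundus rendering keeps the last-drawn color.
    """
    h, w = canvas
    rng = np.random.default_rng(seed)
    class_masks = {ARTERY: np.zeros((h, w), bool), VEIN: np.zeros((h, w), bool)}
    for curve in curves:
        n = max(64, int(4 * _rough_length(curve)))
        pts = curve.sample(n)
        margin = curve.width / 2.0
        if (pts[:, 0].min() < -0.5 + margin - 1 or pts[:, 0].max() > h - 0.5 - margin + 1
                or pts[:, 1].min() < -0.5 + margin - 1 or pts[:, 1].max() > w - 0.5 - margin + 1):
            raise ValueError(f"curve {curve.kind} leaves the {h}x{w} canvas")
        if curve.vessel_class not in class_masks:
            raise ValueError("curves must be artery or vein class")
        _stamp(class_masks[curve.vessel_class], pts, curve.width)

    labels = np.full((h, w), BACKGROUND, dtype=np.uint8)
    labels[class_masks[ARTERY]] = ARTERY
    labels[class_masks[VEIN]] = VEIN
    overlap = class_masks[ARTERY] & class_masks[VEIN]
    if mark_crossings:
        labels[overlap] = UNKNOWN

    img = np.full((h, w, 3), _BACKGROUND_VALUE, dtype=float)
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    for cls in (ARTERY, VEIN):
        color = _VESSEL_COLOR[cls][0]
        img[class_masks[cls]] = color
    if disc_center is not None:
        if disc_radius is None or disc_radius <= 0:
            raise ValueError("disc_radius must be positive when a disc is drawn")
        rr, cc = np.ogrid[0:h, 0:w]
        inside = ((rr - disc_center[0]) ** 2 + (cc - disc_center[1]) ** 2
                  <= disc_radius ** 2)
        img[inside] = _DISC_VALUE
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = PhantomTruth(
        curves=[curve_truth(c) for c in curves],
        disc_center=disc_center,
        disc_radius=disc_radius,
    )
    fundus = FundusImage(pixels, image_id=image_id, eye=eye)
    return fundus, VesselLabelMap(labels, provenance="synthetic"), truth


def _rough_length(curve: CurveSpec) -> float:
    pts = curve.sample(256)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def disc_phantom(canvas: tuple[int, int], center: tuple[float, float],
                 radius: float, seed: int = 0) -> FundusImage:
    """Bright-disc-only phantom for optic disc localization tests."""
    img, _, _ = render_phantom([], canvas=canvas, disc_center=center,
                               disc_radius=radius, seed=seed)
    return img


@dataclasses.dataclass
class PhantomScene:
    image: FundusImage
    labels: VesselLabelMap
    truth: PhantomTruth
    curves: list[CurveSpec]


def sample_population(n_images: int, artery_scale: float = 1.0,
                      tortuosity_level: float = 1.0, seed: int = 0,
                      canvas: tuple[int, int] = (640, 640),
                      ) -> list[PhantomScene]:
    """Draw a seeded cohort of phantom scenes for distribution-level tests.

    Each scene contains 5-15 artery and 5-15 vein curves laid out in
    disjoint horizontal bands (no crossings, none touching the disc), with
    along-axis lengths ~ LogNormal(log 120, 0.25) clipped to [40, 220] px,
    artery lengths multiplied by ``artery_scale`` and sine amplitudes by
    ``tortuosity_level``.  Fully reproducible per seed.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    h, w = canvas
    rng = np.random.default_rng(seed)
    scenes: list[PhantomScene] = []
    disc_center = (80.0, 80.0)
    disc_radius = 40.0
    top, bottom = 150, h - 20
    for idx in range(n_images):
        n_art = int(rng.integers(5, 16))
        n_vein = int(rng.integers(5, 16))
        n_total = n_art + n_vein
        band_h = (bottom - top) / n_total
        classes = np.array([ARTERY] * n_art + [VEIN] * n_vein)
        rng.shuffle(classes)
        curves: list[CurveSpec] = []
        for k, cls in enumerate(classes):
            length = float(np.clip(rng.lognormal(math.log(120.0), 0.25), 40.0, 220.0))
            if cls == ARTERY:
                length = min(length * artery_scale, w - 60.0)
            else:
                length = min(length, w - 60.0)
            amp = float(rng.uniform(2.0, 5.0) * tortuosity_level)
            amp = min(amp, band_h / 2.0 - 2.0)
            row = top + (k + 0.5) * band_h
            col0 = float(rng.uniform(20.0, max(21.0, w - 40.0 - length)))
            if amp < 0.5:
                curves.append(CurveSpec(
                    "line", {"p0": (row, col0), "p1": (row, col0 + length)},
                    width=3, vessel_class=int(cls)))
            else:
                wavelength = float(rng.uniform(60.0, 120.0))
                curves.append(CurveSpec(
                    "sine", {"start": (row, col0), "angle": 0.0,
                             "length": length, "amplitude": amp,
                             "wavelength": wavelength},
                    width=3, vessel_class=int(cls)))
        img, labels, truth = render_phantom(
            curves, canvas=canvas, disc_center=disc_center,
            disc_radius=disc_radius, seed=int(rng.integers(0, 2**31 - 1)),
            image_id=f"phantom-{idx:03d}")
        scenes.append(PhantomScene(img, labels, truth, curves))
    return scenes
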