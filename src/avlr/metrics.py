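"""Per-segment length and tortuosity metrics.

For each centerline segment nine scalars are computed:

========  =====================================================  ==========
name      definition                                             units
========  =====================================================  ==========
chord     Euclidean distance between the path endpoints          px
arc       chain-code length (sum of 1 / sqrt(2) pixel steps)     px
dm        distance metric, ``arc / chord``                       —
icm       inflection count metric, ``(n_inflections + 1) * dm``  —
icmb      like icm with the binomial (normal-flip) count         —
soam      sum of absolute turning angles per unit arc length     rad/px
nc        total absolute curvature per unit arc length           1/px
sdac      standard deviation of pointwise |curvature|            1/px
cl        polyline length of the smoothed sub-pixel centerline   px
========  =====================================================  ==========

Curvature-based quantities are estimated on a smoothed sub-pixel copy of
the raster path: raw chain-code paths only turn in multiples of 45
degrees, so tangent estimates on them are dominated by digitization
jitter.  Smoothing is a truncated moving average of the coordinates
(endpoints retained) followed by a cubic smoothing-spline fit
parameterized by arc length (residual budget ~0.5 px^2 per point, the
digitization noise level), evaluated at ~1 px spacing.  Signed curvature
is the turning angle between consecutive tangents divided by the local
step length.  Exactly collinear paths bypass the spline so straight
vessels report identically zero curvature.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import interpolate

from .skeleton import VesselSegment

#: substituted for the chord of a degenerate (closed) path so ratios stay finite
DEGENERATE_CHORD_EPS = 1e-6

#: spline residual budget per path point (px^2), matched to raster noise
SPLINE_SMOOTHING_PER_POINT = 0.5

#: arc-length spacing (px) at which the smoothed spline is evaluated
RESAMPLE_SPACING = 1.0

#: minimum raster path length for curvature-based metrics
MIN_PATH_PIXELS = 5


@dataclasses.dataclass
class SmoothPath:
    """Smoothed sub-pixel polyline with discrete differential quantities."""

    points: np.ndarray       # (N, 2) float
    step_lengths: np.ndarray  # (N-1,) Euclidean step lengths, all > 0
    tangents: np.ndarray     # (N-1, 2) unit direction per interval
    turning_angles: np.ndarray  # (N-2,) signed angle between tangents, rad
    curvatures: np.ndarray   # (N-2,) signed curvature at interior points, 1/px

    @property
    def length(self) -> float:
        return float(self.step_lengths.sum())


@dataclasses.dataclass
class SegmentMetrics:
    """The nine per-segment values plus bookkeeping flags.

    Curvature-based fields are NaN when the raster path is shorter than
    :data:`MIN_PATH_PIXELS` (``too_short``) — curvature estimation needs at
    least five samples.
    """

    chord: float
    arc: float
    dm: float
    icm: float = math.nan
    icmb: float = math.nan
    soam: float = math.nan
    nc: float = math.nan
    sdac: float = math.nan
    cl: float = math.nan
    n_inflections: int = -1  # -1 when not computed
    too_short: bool = False
    degenerate_chord: bool = False

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("chord", "arc", "dm", "icm", "icmb", "soam", "nc", "sdac", "cl")}


def chord_length(seg: VesselSegment) -> float:
    """Euclidean distance between the first and last path pixels."""
    d = float(np.hypot(*(seg.path[-1] - seg.path[0])))
    return d


def arc_length(seg: VesselSegment) -> float:
    """Chain-code length: 1 per orthogonal step, sqrt(2) per diagonal step."""
    return seg.arc_length()


def _moving_average(points: np.ndarray, window: int) -> np.ndarray:
    """Truncated moving average along axis 0; first/last points retained."""
    n = len(points)
    half = window // 2
    out = np.empty_like(points, dtype=float)
    csum = np.vstack([np.zeros((1, 2)), np.cumsum(points, axis=0)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def _is_collinear(points: np.ndarray) -> bool:
    """True iff every point lies exactly on the first-to-last line."""
    d = points[-1] - points[0]
    rel = points - points[0]
    cross = rel[:, 0] * d[1] - rel[:, 1] * d[0]
    return bool(np.all(cross == 0.0))


def _spline_smooth(points: np.ndarray, spacing: float,
                   smoothing_per_point: float) -> np.ndarray:
    """Fit an arc-length-parameterized cubic smoothing spline, resample it."""
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(steps)])
    total = u[-1]
    if total <= 0:
        return points[[0, -1]].astype(float)
    n_eval = max(5, int(round(total / spacing)) + 1)
    ue = np.linspace(0.0, total, n_eval)
    k = min(3, len(points) - 1)
    try:
        tck, _ = interpolate.splprep(
            [points[:, 0], points[:, 1]], u=u,
            s=len(points) * smoothing_per_point, k=k)
        out = np.array(interpolate.splev(ue, tck)).T
    except (ValueError, TypeError):  # degenerate geometry: linear fallback
        out = np.column_stack([np.interp(ue, u, points[:, 0]),
                               np.interp(ue, u, points[:, 1])])
    return out


def smooth_path(seg: VesselSegment, window: int = 5,
                spacing: float = RESAMPLE_SPACING,
                smoothing_per_point: float = SPLINE_SMOOTHING_PER_POINT,
                ) -> SmoothPath:
    """Smooth and differentiate a raster path.

    ``window`` is the odd moving-average window in pixels applied before
    the spline fit; ``window=1`` is the identity (no smoothing, no
    resampling), useful for analytic paths that are already sub-pixel
    accurate.  Exactly collinear paths skip the spline and report zero
    turning everywhere.
    """
    if len(seg.path) < MIN_PATH_PIXELS:
        raise ValueError(f"path has {len(seg.path)} px < {MIN_PATH_PIXELS}; "
                         "flag the segment too_short instead")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    # work in a local frame anchored at the first pixel so metrics are
    # exactly translation-invariant (spline numerics are not otherwise)
    origin = seg.path[0].astype(float)
    pts = seg.path.astype(float) - origin
    if window > 1 and not _is_collinear(pts):
        pts = _moving_average(pts, window)
        pts = _spline_smooth(pts, spacing, smoothing_per_point)
    # drop zero-length steps (possible only from degenerate input)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    keep = np.concatenate([[True], steps > 1e-12])
    pts = pts[keep]
    diffs = np.diff(pts, axis=0)
    step_lengths = np.linalg.norm(diffs, axis=1)
    tangents = diffs / step_lengths[:, None]
    # signed turning angle between consecutive tangents
    cross = tangents[:-1, 0] * tangents[1:, 1] - tangents[:-1, 1] * tangents[1:, 0]
    dot = np.einsum("ij,ij->i", tangents[:-1], tangents[1:])
    turning = np.arctan2(cross, dot)
    local = 0.5 * (step_lengths[:-1] + step_lengths[1:])
    curvatures = turning / local
    return SmoothPath(points=pts + origin, step_lengths=step_lengths,
                      tangents=tangents, turning_angles=turning,
                      curvatures=curvatures)


def _collapsed_signs(kappa: np.ndarray, smooth_window: int = 5,
                     rel_floor: float = 0.05) -> np.ndarray:
    """Signs of the smoothed curvature with near-zero runs collapsed.

    Values below ``rel_floor`` of the peak smoothed |curvature| (with an
    absolute floor of 1e-9) count as zero and are dropped, so a straight
    run between two bends contributes no spurious alternations.
    """
    if len(kappa) == 0:
        return np.empty(0, dtype=int)
    k = kappa.astype(float)
    if smooth_window > 1 and len(k) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        k = np.convolve(k, kernel, mode="same")
    thresh = max(1e-9, rel_floor * float(np.abs(k).max()))
    signs = np.sign(k[np.abs(k) > thresh]).astype(int)
    if len(signs) == 0:
        return signs
    return signs[np.concatenate([[True], np.diff(signs) != 0])]


def inflection_count(sp: SmoothPath, method: str = "sign_change") -> int:
    """Count interior inflections of a smoothed path.

    ``sign_change``
        Number of sign alternations of the smoothed signed curvature
        (zero runs collapsed) — the standard inflection count.
    ``normal_flip``
        Number of positions where the squared difference of consecutive
        unit Frenet normals exceeds 1 (the classical large-flip criterion
        behind the "binomial" inflection count).
    """
    if method == "sign_change":
        signs = _collapsed_signs(sp.curvatures)
        return max(0, len(signs) - 1)
    if method == "normal_flip":
        signs = np.sign(sp.curvatures)
        # carry the last nonzero sign through flat stretches
        last = 0
        carried = np.empty(len(signs))
        for i, s in enumerate(signs):
            if s != 0:
                last = s
            carried[i] = last if last != 0 else 1.0
        # in-plane normal at interior point i from the mean tangent there
        tmid = sp.tangents[:-1] + sp.tangents[1:]
        norms = np.linalg.norm(tmid, axis=1)
        norms[norms == 0] = 1.0
        tmid = tmid / norms[:, None]
        perp = np.column_stack([-tmid[:, 1], tmid[:, 0]])
        normals = perp * carried[:, None]
        d2 = np.sum(np.diff(normals, axis=0) ** 2, axis=1)
        return int((d2 > 1.0).sum())
    raise ValueError(f"unknown inflection method {method!r}")


def metrics_for_segment(seg: VesselSegment, window: int = 5,
                        spacing: float = RESAMPLE_SPACING) -> SegmentMetrics:
    """Compute all nine metrics for one segment.

    Paths shorter than :data:`MIN_PATH_PIXELS` get chord/arc/dm only and a
    ``too_short`` flag; closed paths (coincident endpoints) get an epsilon
    chord and a ``degenerate_chord`` flag rather than a division error.
    """
    chord = chord_length(seg)
    degenerate = chord < DEGENERATE_CHORD_EPS
    if degenerate:
        chord = DEGENERATE_CHORD_EPS
    arc = arc_length(seg)
    dm = arc / chord
    if len(seg.path) < MIN_PATH_PIXELS:
        return SegmentMetrics(chord=chord, arc=arc, dm=dm, too_short=True,
                              degenerate_chord=degenerate)
    sp = smooth_path(seg, window=window, spacing=spacing)
    n_infl = inflection_count(sp, "sign_change")
    n_flip = inflection_count(sp, "normal_flip")
    abs_kappa = np.abs(sp.curvatures)
    local = 0.5 * (sp.step_lengths[:-1] + sp.step_lengths[1:])
    total_turning = float(np.abs(sp.turning_angles).sum())
    return SegmentMetrics(
        chord=chord,
        arc=arc,
        dm=dm,
        icm=(n_infl + 1) * dm,
        icmb=(n_flip + 1) * dm,
        soam=total_turning / arc,
        nc=float((abs_kappa * local).sum()) / arc,
        sdac=float(abs_kappa.std()) if len(abs_kappa) else 0.0,
        cl=sp.length,
        n_inflections=n_infl,
        too_short=False,
        degenerate_chord=degenerate,
    )
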