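import math

import numpy as np
import pytest

from avlr import metrics_for_segment, segments_from_labels
from avlr.synthetic import CurveSpec, render_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def single_segment(curve: CurveSpec, canvas=(400, 400)):
    """Render one curve, run the centerline stage, return its lone segment."""
    _, labels, truth = render_phantom([curve], canvas=canvas)
    segs = segments_from_labels(labels)
    assert len(segs) == 1, f"expected 1 segment, got {len(segs)}"
    return segs[0], truth.curves[0]


def semicircle(radius: float, center=None, width=3, vessel_class=1) -> CurveSpec:
    if center is None:
        center = (radius + 60.0, radius + 60.0)
    return CurveSpec(
        "circular_arc",
        {"center": center, "radius": radius,
         "theta0": -math.pi / 2, "theta1": math.pi / 2},
        width=width, vessel_class=vessel_class,
    )


def sine_curve(periods: int, amplitude=20.0, wavelength=100.0, start=(60, 20),
               angle=0.0, width=3, vessel_class=1) -> CurveSpec:
    return CurveSpec(
        "sine",
        {"start": start, "angle": angle, "length": periods * wavelength,
         "amplitude": amplitude, "wavelength": wavelength},
        width=width, vessel_class=vessel_class,
    )


@pytest.fixture
def semicircle_metrics():
    """Pipeline metrics + truth for semicircles of several radii."""
    out = {}
    for r in (30, 50, 100):
        seg, truth = single_segment(semicircle(r), canvas=(2 * r + 120, 2 * r + 120))
        out[r] = (metrics_for_segment(seg), truth)
    return out
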