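"""Annular regions of interest around the optic disc.

The morphometry is computed inside ring cuts whose radii are multiples of
the optic disc radius (ROD): the standard rings span 2-3 ROD and 2-5 ROD.
Membership uses the half-open interval ``[inner*R, outer*R)`` on Euclidean
distance between pixel centers, so adjacent rings sharing a radius
partition the plane without double counting.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import BACKGROUND, VesselLabelMap
from .optic_disc import OpticDisc


@dataclasses.dataclass(frozen=True)
class RingROI:
    disc: OpticDisc
    inner_factor: float = 2.0
    outer_factor: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.inner_factor < self.outer_factor:
            raise ValueError("require 0 <= inner_factor < outer_factor")

    @property
    def name(self) -> str:
        def fmt(x: float) -> str:
            return f"{x:g}"
        return f"{fmt(self.inner_factor)}-{fmt(self.outer_factor)}ROD"


def ring_mask(roi: RingROI, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the annulus ``inner*R <= dist < outer*R`` on a canvas."""
    h, w = shape
    if h < 1 or w < 1:
        raise ValueError("shape must be positive")
    cr, cc = roi.disc.center
    rr, cc_grid = np.ogrid[0:h, 0:w]
    dist = np.hypot(rr - cr, cc_grid - cc)
    r = roi.disc.radius
    return (roi.inner_factor * r <= dist) & (dist < roi.outer_factor * r)


def clip_labels(labels: VesselLabelMap, roi: RingROI) -> VesselLabelMap:
    """Zero out every label pixel outside the ring (vessels truncated at the rim)."""
    mask = ring_mask(roi, labels.shape)
    out = labels.classes.copy()
    out[~mask] = BACKGROUND
    return VesselLabelMap(out, provenance=labels.provenance)
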