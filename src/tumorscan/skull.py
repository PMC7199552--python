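"""Skull-edge extraction, brain-size measurement, and the distance threshold.

The largest surrounding edge — the biggest connected outline of the
bright+medium intensity clusters — is taken to be the skull. It is kept (not
stripped) and used twice: eroded inward to mask out skull-attached bright
rims, and as the reference for the Euclidean-distance rejection of
candidates that sit too close to it. The rejection threshold scales with
brain size through a piecewise-linear map anchored at
(5000 px, 5), (8000 px, 6), (100000 px, 25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask

# 3x3 cross (city-block) structuring element used for the inward erosion.
CROSS_KERNEL = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# (brain_pixels, distance_threshold) anchors of the size->threshold map.
DEFAULT_ANCHORS: tuple[tuple[float, float], ...] = ((5000.0, 5.0), (8000.0, 6.0), (100000.0, 25.0))

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class SkullModel:
    """Skull outline plus the quantities derived from it."""

    edge: BinaryMask
    filled: BinaryMask
    brain_pixels: int
    distance_threshold: float


def largest_surrounding_edge(bright: BinaryMask, medium: BinaryMask) -> BinaryMask:
    """Outline of the bright+medium union; largest 8-connected component.

    A pixel is *interior* when all four of its edge-neighbors are set;
    removing interior pixels leaves the component boundaries. The biggest
    boundary component is the skull outline for any head-bearing image.
    """
    bright = np.asarray(bright, bool)
    medium = np.asarray(medium, bool)
    if bright.shape != medium.shape:
        raise ValueError("mask shapes differ")
    union = bright | medium
    if not union.any():
        raise ValueError("no brain found: bright+medium union is empty")
    # erosion with the cross = "all 4-neighbors set"; border pixels are not interior
    interior = ndimage.binary_erosion(union, structure=CROSS_KERNEL, border_value=0)
    outline = union & ~interior
    labels, n = ndimage.label(outline, structure=_EIGHT)
    if n == 0:
        return outline
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def fill_and_measure(
    edge: BinaryMask, anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
) -> SkullModel:
    """Fill the holes of the edge and measure brain size.

    Background is whatever is reachable from the image border through
    4-connected non-edge pixels; everything else counts as brain. An open
    (C-shaped) edge lets the fill leak, so ``filled`` degenerates to the
    edge itself — documented behavior, not an error.
    """
    edge = np.asarray(edge, bool)
    if not edge.any():
        raise ValueError("empty edge")
    filled = ndimage.binary_fill_holes(edge, structure=CROSS_KERNEL)
    brain_pixels = int(filled.sum())
    return SkullModel(
        edge=edge,
        filled=filled,
        brain_pixels=brain_pixels,
        distance_threshold=distance_threshold_from_size(brain_pixels, anchors),
    )


def distance_threshold_from_size(
    brain_pixels: int, anchors: tuple[tuple[float, float], ...] = DEFAULT_ANCHORS
) -> float:
    """Map brain area (pixels) to the skull-distance rejection threshold.

    Piecewise-linear through the anchor points, extrapolated with the
    nearest segment's slope, and clamped to a floor of 3 px so tiny brains
    still reject edge-touching candidates.
    """
    if brain_pixels <= 0:
        raise ValueError("brain_pixels must be positive")
    pts = sorted(anchors)
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    x = float(brain_pixels)
    if x <= xs[0]:
        i = 0
    elif x >= xs[-1]:
        i = len(xs) - 2
    else:
        i = int(np.searchsorted(xs, x, side="right")) - 1
    slope = (ys[i + 1] - ys[i]) / (xs[i + 1] - xs[i])
    return max(3.0, float(ys[i] + slope * (x - xs[i])))


def expand_edge_inward(skull: SkullModel, iterations: int = 10) -> BinaryMask:
    """Band of ~``iterations`` px just inside the skull boundary.

    Computed as ``filled AND NOT erode(filled, cross, iterations)``; bands
    are nested in the iteration count and iteration 0 is empty.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    filled = np.asarray(skull.filled, bool)
    if iterations == 0:
        return np.zeros_like(filled)
    eroded = ndimage.binary_erosion(filled, structure=CROSS_KERNEL, iterations=iterations, border_value=0)
    return filled & ~eroded
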