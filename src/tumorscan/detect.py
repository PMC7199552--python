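"""Per-patch tumor candidate detection.

Each (upscaled) patch is scanned twice — once as-is and once after a
30-70% contrast stretch that boosts low-contrast lesions. A scan smooths
the patch, zeroes near-black speckle, binarizes at a ladder of thresholds
(0.1, 0.3, 0.5, 0.7, 0.9 plus the patch's Otsu cut), removes small
objects, fills holes, and sums the binary layers into an accumulation
image. Candidates are then peeled off iteratively: the connected component
holding the maximum accumulated value is eroded with growing Euclidean
disks until a single object survives, a region is grown from that
survivor's center, and the grown region is recorded and cleared from the
accumulation before the next round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .io import BinaryMask, GrayImage, contrast_stretch
from .preprocess import mean_filter

_EIGHT = np.ones((3, 3), dtype=bool)
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class DetectionParams:
    """Knobs of the per-patch scan.

    thresholds
        Fixed binarization levels, each in (0, 1).
    use_otsu
        Append the per-patch Otsu threshold to the ladder (skipped for
        constant patches).
    min_object_area
        Connected components smaller than this (pixels at working scale)
        are treated as noise and dropped from every binary layer. The
        default of 80 sits above both single-pixel noise spikes after 3x
        bilinear upscaling (~25-30 px) and unmagnified small lesions (a
        radius-3 disk plus its smoothing halo covers under ~60 px), yet
        below the smallest magnified target lesion (radius 2 px -> ~100 px
        at 3x scale) — so detecting small lesions genuinely requires the
        patch magnification.
    grow_delta
        Region growing admits 8-connected pixels whose intensity is within
        this much below the seed intensity.
    contrast_pass_window
        Stretch window of the second scan.
    max_candidates
        Cap on candidate-peeling rounds per patch (termination guarantee).
    low_intensity_cutoff
        Pixels below this are zeroed before thresholding.
    """

    thresholds: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    use_otsu: bool = True
    min_object_area: int = 80
    grow_delta: float = 0.2
    contrast_pass_window: tuple[float, float] = (0.30, 0.70)
    max_candidates: int = 20
    low_intensity_cutoff: float = 0.05

    def __post_init__(self) -> None:
        if any(not 0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")
        if not 0.0 < self.grow_delta < 1.0:
            raise ValueError("grow_delta must lie in (0, 1)")


def otsu_threshold(patch: GrayImage) -> float:
    """Otsu's between-class-variance-maximizing cut on a 256-bin histogram."""
    patch = np.asarray(patch, np.float64)
    if patch.size == 0 or float(patch.min()) == float(patch.max()):
        raise ValueError("Otsu threshold undefined for a constant patch")
    return float(threshold_otsu(patch, nbins=256))


def count_objects(mask: BinaryMask) -> int:
    """Number of 8-connected components of True pixels."""
    _, n = ndimage.label(np.asarray(mask, bool), structure=_EIGHT)
    return int(n)


def erode_until_single(mask: BinaryMask) -> tuple[BinaryMask, int]:
    """Erode with Euclidean disks of growing radius until one object remains.

    The erosion of a mask by the discrete disk of radius ``r`` (all offsets
    of Euclidean norm <= r) equals the set of pixels whose Euclidean
    distance to the nearest background pixel exceeds ``r``, so a single
    distance transform yields every radius at once. If the component count
    jumps from >= 2 straight to 0, the largest component of the last
    nonzero erosion is returned with that radius (area ties broken by
    topmost-then-leftmost centroid).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("cannot erode an empty mask")
    # pad so pixels outside the image count as background, like true erosion
    dist = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    r = 0
    while True:
        eroded = dist > r
        if not eroded.any():
            # jumped past extinction: keep the largest piece of radius r-1
            prev = dist > (r - 1)
            labels, n = ndimage.label(prev, structure=_EIGHT)
            return _largest_component(labels, n), r - 1
        labels, n = ndimage.label(eroded, structure=_EIGHT)
        if n == 1:
            return eroded, r
        r += 1


def _largest_component(labels: np.ndarray, n: int) -> BinaryMask:
    """Largest labeled component; ties go to the topmost-then-leftmost centroid."""
    counts = np.bincount(labels.ravel())[1 : n + 1]
    best = counts.max()
    tied = np.flatnonzero(counts == best) + 1
    if len(tied) == 1:
        return labels == tied[0]
    cents = ndimage.center_of_mass(np.ones_like(labels), labels, tied)
    order = sorted(range(len(tied)), key=lambda i: (cents[i][0], cents[i][1]))
    return labels == tied[order[0]]


def region_grow(
    img: GrayImage, seed: tuple[int, int], delta: float, floor: float = 0.0
) -> BinaryMask:
    """8-connected flood from ``seed`` over pixels >= seed intensity - delta.

    ``floor`` puts a lower bound on admissible intensity regardless of the
    seed; without it a seed dimmer than ``delta`` would flood the zero
    background.
    """
    img = np.asarray(img, np.float64)
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < img.shape[0] and 0 <= c < img.shape[1]):
        raise IndexError(f"seed {seed} outside image of shape {img.shape}")
    admissible = img >= max(img[r, c] - delta, floor)
    if not admissible[r, c]:  # floor excludes even the seed: degenerate region
        out = np.zeros(img.shape, dtype=bool)
        out[r, c] = True
        return out
    labels, _ = ndimage.label(admissible, structure=_EIGHT)
    return labels == labels[r, c]


def _interior_seed(mask: BinaryMask) -> tuple[int, int]:
    """Mask pixel nearest the mask centroid (the centroid itself may fall outside)."""
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    i = int(np.argmin((rows - cr) ** 2 + (cols - cc) ** 2))
    return int(rows[i]), int(cols[i])


def _accumulate(patch: GrayImage, params: DetectionParams) -> np.ndarray:
    """Sum of cleaned binary layers over the threshold ladder."""
    work = patch.copy()
    work[work < params.low_intensity_cutoff] = 0.0
    levels = list(params.thresholds)
    if params.use_otsu and float(work.min()) != float(work.max()):
        levels.append(otsu_threshold(work))
    acc = np.zeros(patch.shape, dtype=np.int32)
    for t in levels:
        binary = work > t
        if not binary.any():
            continue
        labels, n = ndimage.label(binary, structure=_EIGHT)
        counts = np.bincount(labels.ravel())
        keep = counts >= params.min_object_area
        keep[0] = False
        binary = keep[labels]
        if binary.any():
            binary = ndimage.binary_fill_holes(binary, structure=_CROSS)
            acc += binary
    return acc


def _peel_candidates(acc: np.ndarray, grow_img: GrayImage, params: DetectionParams) -> BinaryMask:
    """Iteratively isolate and grow candidates out of an accumulation image."""
    out = np.zeros(acc.shape, dtype=bool)
    acc = acc.copy()
    for _ in range(params.max_candidates):
        peak = acc.max()
        if peak == 0:
            break
        labels, n = ndimage.label(acc > 0, structure=_EIGHT)
        # components containing the maximum accumulated value
        peak_labels = np.unique(labels[acc == peak])
        sub = np.isin(labels, peak_labels) & (labels > 0)
        sub_labels, sub_n = ndimage.label(sub, structure=_EIGHT)
        comp = _largest_component(sub_labels, sub_n)
        survivor, _ = erode_until_single(comp)
        seed = _interior_seed(survivor)
        grown = region_grow(grow_img, seed, params.grow_delta, floor=params.low_intensity_cutoff)
        out |= grown
        acc[grown] = 0
        acc[comp] = 0
    return out


def detect_in_patch(patch: GrayImage, params: DetectionParams | None = None) -> BinaryMask:
    """Candidate mask for one working-scale patch (union of both scans)."""
    params = params or DetectionParams()
    patch = np.asarray(patch, np.float64)
    out = np.zeros(patch.shape, dtype=bool)
    if patch.size == 0 or not patch.any():
        return out
    for stretched in (False, True):
        img = contrast_stretch(patch, *params.contrast_pass_window) if stretched else patch
        smoothed = mean_filter(img, 3)
        acc = _accumulate(smoothed, params)
        out |= _peel_candidates(acc, smoothed, params)
    return out
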