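"""Construction of the detection input image.

Two modified images are combined: (1) the cerebral mask — the medium
intensity cluster with the inward-eroded skull band removed, reduced to its
largest component and hole-filled; (2) the focus image — a box-smoothed
copy of the slice multiplied by a near-binarization of the same slice at
mid intensity (window 49.99-50.01%), then re-windowed to 10-90%. Their
product suppresses background, skull, and skull-attached rims while keeping
bright interior structure for the patch scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import BinaryMask, GrayImage, contrast_stretch
from .skull import CROSS_KERNEL, _EIGHT


@dataclass
class PreprocessConfig:
    avg_kernel_size: int = 3
    narrow_window: tuple[float, float] = (0.4999, 0.5001)
    wide_window: tuple[float, float] = (0.10, 0.90)

    def __post_init__(self) -> None:
        if self.avg_kernel_size < 1 or self.avg_kernel_size % 2 == 0:
            raise ValueError("avg_kernel_size must be odd and >= 1")
        for lo, hi in (self.narrow_window, self.wide_window):
            if not lo < hi:
                raise ValueError(f"window requires lo < hi, got ({lo}, {hi})")


def mean_filter(img: GrayImage, size: int) -> GrayImage:
    """Box mean with reflect padding at the borders."""
    return ndimage.uniform_filter(np.asarray(img, np.float64), size=size, mode="reflect")


def cerebral_mask(medium: BinaryMask, inward_band: BinaryMask) -> BinaryMask:
    """Cerebrum support: medium cluster minus the inner skull band.

    The difference is reduced to its largest 8-connected component, whose
    holes are then filled (component first, fill second).
    """
    medium = np.asarray(medium, bool)
    inward_band = np.asarray(inward_band, bool)
    if medium.shape != inward_band.shape:
        raise ValueError("mask shapes differ")
    core = medium & ~inward_band
    labels, n = ndimage.label(core, structure=_EIGHT)
    if n == 0:
        raise ValueError("no cerebral tissue found")
    counts = np.bincount(labels.ravel())[1:]
    largest = labels == (int(np.argmax(counts)) + 1)
    return ndimage.binary_fill_holes(largest, structure=CROSS_KERNEL)


def focus_image(img: GrayImage, cfg: PreprocessConfig | None = None) -> GrayImage:
    """Contrast-focused copy of the slice emphasizing above-mid intensities."""
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, np.float64)
    smoothed = mean_filter(img, cfg.avg_kernel_size)
    gate = contrast_stretch(img, *cfg.narrow_window)
    return contrast_stretch(smoothed * gate, *cfg.wide_window)


def modified_image(img: GrayImage, cereb: BinaryMask, cfg: PreprocessConfig | None = None) -> GrayImage:
    """Detection input: cerebral mask (as 0/1) times the focus image."""
    cereb = np.asarray(cereb, bool)
    img = np.asarray(img, np.float64)
    if img.shape != cereb.shape:
        raise ValueError("image and mask shapes differ")
    return cereb.astype(np.float64) * focus_image(img, cfg)
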