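"""Image and report I/O plus the intensity-window primitive.

All images are handled internally as ``GrayImage``: a 2-D float64 array with
every value in [0, 1], 0-based (row, col) coordinates. Loading min-max
normalizes whatever bit depth arrives; a constant image maps to all zeros.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

# GrayImage / BinaryMask are plain ndarrays; these aliases document intent.
GrayImage = np.ndarray
BinaryMask = np.ndarray


def _as_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a multichannel array to single-channel luminance."""
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 3:
        if a.shape[2] == 4:  # drop alpha
            a = a[:, :, :3]
        if a.shape[2] == 3:
            a = a @ np.array([0.2125, 0.7154, 0.0721])
        else:
            a = a[:, :, 0]
    if a.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {a.shape}")
    return a


def normalize(arr: np.ndarray) -> GrayImage:
    """Min-max normalize an array to [0, 1]; a zero-range image maps to 0."""
    a = _as_gray(arr)
    if a.size == 0:
        raise ValueError("empty image")
    lo = float(a.min())
    hi = float(a.max())
    if hi == lo:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def load_image(path: str | Path, slice_index: int | None = None) -> GrayImage:
    """Load a PNG/TIFF image or one axial slice of a NIfTI volume.

    Parameters
    ----------
    path
        File to read. ``.nii`` / ``.nii.gz`` are read through nibabel; any
        other extension goes through imageio.
    slice_index
        Axial slice to extract from a NIfTI volume (last axis). Defaults to
        the middle slice. Ignored for 2-D raster formats.

    Returns
    -------
    GrayImage
        Min-max normalized 2-D float array in [0, 1].
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such file: {p}")
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(str(p)).dataobj, dtype=np.float64)
        if vol.ndim == 2:
            arr = vol
        else:
            vol = vol.reshape(vol.shape[0], vol.shape[1], -1)
            idx = vol.shape[2] // 2 if slice_index is None else slice_index
            if not 0 <= idx < vol.shape[2]:
                raise IndexError(
                    f"slice_index {idx} out of range for volume with {vol.shape[2]} slices"
                )
            arr = vol[:, :, idx]
    else:
        import imageio.v3 as iio

        try:
            arr = iio.imread(p)
        except Exception as exc:  # pragma: no cover - backend-specific message
            raise IOError(f"cannot read image {p}: {exc}") from exc
    return normalize(arr)


def contrast_stretch(img: GrayImage, lo: float, hi: float) -> GrayImage:
    """Linear window-and-clip: ``clip((x - lo) / (hi - lo), 0, 1)``.

    A narrow window such as (0.4999, 0.5001) acts as a near-binarization at
    mid-intensity; (0.10, 0.90) spreads the central intensity range to the
    full scale. Monotone non-decreasing in the input for any fixed window.
    """
    if not lo < hi:
        raise ValueError(f"require lo < hi, got ({lo}, {hi})")
    img = np.asarray(img, dtype=np.float64)
    return np.clip((img - lo) / (hi - lo), 0.0, 1.0)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a mask PNG back to boolean (any nonzero pixel is True)."""
    import imageio.v3 as iio

    return _as_gray(iio.imread(Path(path))) > 0


def write_report(report: "DetectionReport | dict", path: str | Path) -> None:
    """Serialize a detection report to JSON (lossless round trip)."""
    data = report.to_dict() if hasattr(report, "to_dict") else report
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
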