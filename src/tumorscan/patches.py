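"""Patch tiling, 3x upscaling, shift voting.

The detection image is tiled into 200x200 patches, each patch is upscaled
3x (bilinear) so small lesions present enough pixels to survive the
small-object filter, scanned, and the result mapped back. The whole tiling
is repeated under 50-pixel grid shifts; each shift contributes one vote per
pixel and pixels voted at least ``min_votes`` times become candidates,
suppressing patch-boundary artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import block_reduce
from skimage.transform import resize

from .detect import DetectionParams, detect_in_patch
from .io import BinaryMask, GrayImage

DEFAULT_SHIFTS: tuple[tuple[int, int], ...] = ((0, 0), (0, 50), (0, 100), (0, 150))


@dataclass
class PatchGrid:
    patch_size: int
    offset: tuple[int, int]
    padded_shape: tuple[int, int]
    origins: list  # (row, col) of each patch in original coordinates
    patches: list  # GrayImage tiles, patch_size x patch_size


@dataclass
class VoteMap:
    votes: np.ndarray
    n_passes: int


def split_patches(img: GrayImage, patch_size: int = 200, offset: tuple[int, int] = (0, 0)) -> PatchGrid:
    """Tile the image into non-overlapping patches on a shifted grid.

    The grid origin sits at ``-offset``; the image is zero-padded on the
    top/left by the offset and on the right/bottom up to a multiple of
    ``patch_size``. Patch origins are recorded in original coordinates (the
    top-left patches start at negative coordinates when shifted).
    """
    if patch_size < 1:
        raise ValueError("patch_size must be >= 1")
    oy, ox = offset
    if not (0 <= oy < patch_size and 0 <= ox < patch_size):
        raise ValueError("offsets must lie in [0, patch_size)")
    img = np.asarray(img, np.float64)
    h, w = img.shape
    ny = -(-(h + oy) // patch_size)
    nx = -(-(w + ox) // patch_size)
    padded = np.zeros((ny * patch_size, nx * patch_size), dtype=np.float64)
    padded[oy : oy + h, ox : ox + w] = img
    origins = []
    tiles = []
    for i in range(ny):
        for j in range(nx):
            r0, c0 = i * patch_size, j * patch_size
            origins.append((r0 - oy, c0 - ox))
            tiles.append(padded[r0 : r0 + patch_size, c0 : c0 + patch_size])
    return PatchGrid(
        patch_size=patch_size,
        offset=(oy, ox),
        padded_shape=padded.shape,
        origins=origins,
        patches=tiles,
    )


def upscale(patch: GrayImage, scale: int = 3) -> GrayImage:
    """Bilinear upscaling to (scale*h, scale*w); scale 1 is the identity."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    patch = np.asarray(patch, np.float64)
    if scale == 1:
        return patch
    out_shape = (patch.shape[0] * scale, patch.shape[1] * scale)
    return resize(patch, out_shape, order=1, mode="edge", anti_aliasing=False, preserve_range=True)


def downscale_mask(mask: BinaryMask, scale: int, target_shape: tuple[int, int]) -> BinaryMask:
    """Majority block-reduce: output pixel True iff >= half its block is True."""
    mask = np.asarray(mask, bool)
    if scale == 1:
        reduced = mask
    else:
        if mask.shape[0] % scale or mask.shape[1] % scale:
            raise ValueError(f"mask shape {mask.shape} not divisible by scale {scale}")
        reduced = block_reduce(mask.astype(np.float64), (scale, scale), np.mean) >= 0.5
    if reduced.shape != tuple(target_shape):
        raise ValueError(f"reduced shape {reduced.shape} != target {tuple(target_shape)}")
    return reduced


def _single_pass(
    img: GrayImage,
    params: DetectionParams,
    offset: tuple[int, int],
    patch_size: int,
    scale: int,
) -> BinaryMask:
    """One shifted tiling pass: split, upscale, detect, stitch back."""
    grid = split_patches(img, patch_size, offset)
    h, w = img.shape
    oy, ox = grid.offset
    stitched = np.zeros(grid.padded_shape, dtype=bool)
    for (r0, c0), tile in zip(grid.origins, grid.patches):
        if not tile.any():  # nothing to detect in an all-zero tile
            continue
        found = detect_in_patch(upscale(tile, scale), params)
        reduced = downscale_mask(found, scale, tile.shape)
        pr, pc = r0 + oy, c0 + ox
        stitched[pr : pr + patch_size, pc : pc + patch_size] = reduced
    return stitched[oy : oy + h, ox : ox + w]


def run_passes(
    img: GrayImage,
    params: DetectionParams | None = None,
    shifts: tuple[tuple[int, int], ...] = DEFAULT_SHIFTS,
    patch_size: int = 200,
    scale: int = 3,
) -> VoteMap:
    """Detection under every grid shift; one vote per shift per pixel."""
    if not shifts:
        raise ValueError("shifts must be nonempty")
    params = params or DetectionParams()
    img = np.asarray(img, np.float64)
    votes = np.zeros(img.shape, dtype=np.int32)
    for shift in shifts:
        votes += _single_pass(img, params, tuple(shift), patch_size, scale)
    return VoteMap(votes=votes, n_passes=len(shifts))


def select_candidates(vm: VoteMap, min_votes: int = 2) -> BinaryMask:
    """Pixels detected in at least ``min_votes`` passes."""
    if not 1 <= min_votes <= vm.n_passes:
        raise ValueError(f"min_votes must lie in [1, {vm.n_passes}]")
    return vm.votes >= min_votes
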