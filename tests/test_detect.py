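"""Per-patch detection primitives against independent oracles."""

from collections import deque

import numpy as np
import pytest
from scipy import ndimage

from tumorscan import (
    DetectionParams,
    count_objects,
    detect_in_patch,
    erode_until_single,
    otsu_threshold,
    region_grow,
)


def bfs_count(mask: np.ndarray) -> int:
    """Breadth-first-search flood-fill component count (8-connectivity)."""
    mask = np.asarray(mask, bool)
    seen = np.zeros_like(mask)
    count = 0
    h, w = mask.shape
    for sr in range(h):
        for sc in range(w):
            if mask[sr, sc] and not seen[sr, sc]:
                count += 1
                q = deque([(sr, sc)])
                seen[sr, sc] = True
                while q:
                    r, c = q.popleft()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                                seen[rr, cc] = True
                                q.append((rr, cc))
    return count


def exhaustive_otsu(patch: np.ndarray, nbins: int = 256) -> float:
    """Scan every histogram cut for the maximal between-class variance."""
    hist, edges = np.histogram(patch.ravel(), bins=nbins, range=(patch.min(), patch.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best_var, best_t = -1.0, centers[0]
    for cut in range(1, nbins):
        w0, w1 = hist[:cut].sum(), hist[cut:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:cut] * centers[:cut]).sum() / w0
        m1 = (hist[cut:] * centers[cut:]).sum() / w1
        var = (w0 / total) * (w1 / total) * (m0 - m1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[cut - 1]
    return float(best_t)


def disk(radius: int) -> np.ndarray:
    """Discrete Euclidean disk: all offsets with norm <= radius."""
    r = np.arange(-radius, radius + 1)
    return (r[:, None] ** 2 + r[None, :] ** 2) <= radius**2


class TestOtsu:
    def test_bimodal_split(self):
        rng = np.random.default_rng(0)
        patch = np.where(rng.random((20, 20)) < 0.5, 0.2, 0.8)
        t = otsu_threshold(patch)
        assert 0.2 < t < 0.8
        assert set(np.unique(patch > t)) == {False, True}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        patch = np.random.default_rng(seed).random((30, 30))
        t = otsu_threshold(patch)
        oracle = exhaustive_otsu(patch)
        # agreement to within one histogram bin
        assert abs(t - oracle) <= (patch.max() - patch.min()) / 256 + 1e-12

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        patch = rng.random((10, 10))
        shuffled = rng.permutation(patch.ravel()).reshape(10, 10)
        assert otsu_threshold(patch) == pytest.approx(otsu_threshold(shuffled))

    def test_constant_patch_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.full((5, 5), 0.7))


class TestCountObjects:
    def test_three_disks(self):
        mask = np.zeros((40, 40), bool)
        for center in ((10, 10), (10, 30), (30, 20)):
            rr, cc = np.mgrid[0:40, 0:40]
            mask |= np.hypot(rr - center[0], cc - center[1]) <= 4
        assert count_objects(mask) == 3

    def test_empty_mask(self):
        assert count_objects(np.zeros((5, 5), bool)) == 0

    def test_matches_bfs_oracle_on_random_masks(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            mask = rng.random((30, 30)) < rng.uniform(0.05, 0.6)
            assert count_objects(mask) == bfs_count(mask)


class TestErodeUntilSingle:
    def test_single_component_returns_identity(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        survivor, radius = erode_until_single(mask)
        assert radius == 0
        np.testing.assert_array_equal(survivor, mask)

    def test_small_disk_vanishes_first(self):
        rr, cc = np.mgrid[0:60, 0:60]
        big = np.hypot(rr - 20, cc - 20) <= 10
        small = np.hypot(rr - 45, cc - 45) <= 2
        survivor, radius = erode_until_single(big | small)
        assert radius <= 3
        assert (survivor & big).any() and not (survivor & small).any()
        # survivor is the disk-erosion of the original at that radius
        oracle = ndimage.binary_erosion(big | small, structure=disk(radius)) if radius else (big | small)
        np.testing.assert_array_equal(survivor, oracle)

    def test_equal_disks_trigger_extinction_fallback(self):
        rr, cc = np.mgrid[0:40, 0:80]
        a = np.hypot(rr - 20, cc - 20) <= 5
        b = np.hypot(rr - 20, cc - 60) <= 5
        survivor, radius = erode_until_single(a | b)
        assert count_objects(survivor) == 1
        assert not (survivor & ~(a | b)).any()
        # both shrink equally, so the jump was from 2 components to 0
        eroded_next = ndimage.binary_erosion(a | b, structure=disk(radius + 1))
        assert not eroded_next.any()

    def test_radius_is_minimal(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            mask = ndimage.binary_dilation(rng.random((30, 30)) < 0.05, iterations=2)
            if not mask.any():
                continue
            survivor, radius = erode_until_single(mask)
            assert not (survivor & ~mask).any()
            if radius > 0:
                prev = ndimage.binary_erosion(mask, structure=disk(radius - 1)) if radius > 1 else mask
                labels, n = ndimage.label(prev, structure=np.ones((3, 3), bool))
                assert n != 1

    def test_edt_shortcut_equals_disk_erosion(self):
        """Erosion by a Euclidean disk of radius r equals EDT(mask) > r."""
        rng = np.random.default_rng(9)
        for _ in range(10):
            mask = ndimage.binary_dilation(rng.random((25, 25)) < 0.08, iterations=3)
            d = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
            for r in range(4):
                oracle = ndimage.binary_erosion(mask, structure=disk(r)) if r else mask
                np.testing.assert_array_equal(d > r, oracle)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            erode_until_single(np.zeros((4, 4), bool))


class TestRegionGrow:
    def test_full_delta_floods_bright_image(self):
        img = np.ones((10, 10))
        grown = region_grow(img, (5, 5), 1.0)
        assert grown.all()

    def test_zero_delta_recovers_flat_disk(self):
        img = np.zeros((30, 30))
        rr, cc = np.mgrid[0:30, 0:30]
        disk_mask = np.hypot(rr - 15, cc - 15) <= 6
        img[disk_mask] = 0.8
        grown = region_grow(img, (15, 15), 0.0)
        np.testing.assert_array_equal(grown, disk_mask)

    def test_contains_seed(self):
        rng = np.random.default_rng(10)
        img = rng.random((12, 12))
        assert region_grow(img, (3, 4), 0.1)[3, 4]

    def test_floor_blocks_background_flood(self):
        img = np.zeros((10, 10))
        img[4, 4] = 0.1
        assert region_grow(img, (4, 4), 0.5).all()  # dim seed floods without a floor
        grown = region_grow(img, (4, 4), 0.5, floor=0.05)
        assert grown.sum() == 1

    def test_out_of_bounds_seed(self):
        with pytest.raises(IndexError):
            region_grow(np.zeros((5, 5)), (9, 0), 0.2)


class TestDetectInPatch:
    def test_all_zero_patch_empty(self):
        assert not detect_in_patch(np.zeros((50, 50))).any()

    def test_single_disk_high_dice(self):
        img = np.zeros((120, 120))
        rr, cc = np.mgrid[0:120, 0:120]
        disk_mask = np.hypot(rr - 60, cc - 60) <= 15
        img[disk_mask] = 0.9
        found = detect_in_patch(img)
        inter = (found & disk_mask).sum()
        dice = 2 * inter / (found.sum() + disk_mask.sum())
        assert dice >= 0.8

    def test_two_disks_of_different_brightness_both_found(self):
        img = np.zeros((140, 140))
        rr, cc = np.mgrid[0:140, 0:140]
        d1 = np.hypot(rr - 40, cc - 40) <= 12
        d2 = np.hypot(rr - 100, cc - 100) <= 12
        img[d1] = 0.95
        img[d2] = 0.6
        found = detect_in_patch(img)
        assert (found & d1).sum() > 0.5 * d1.sum()
        assert (found & d2).sum() > 0.5 * d2.sum()

    def test_deterministic_and_bounded(self):
        rng = np.random.default_rng(11)
        img = np.clip(rng.random((80, 80)) * 0.3, 0, 1)
        img[20:40, 20:40] = 0.9
        a, b = detect_in_patch(img), detect_in_patch(img)
        np.testing.assert_array_equal(a, b)
        assert a.shape == img.shape

    def test_small_objects_removed_and_holes_filled(self):
        params = DetectionParams(min_object_area=30)
        img = np.zeros((100, 100))
        img[10, 10] = 0.9  # single-pixel speck, below area cutoff
        rr, cc = np.mgrid[0:100, 0:100]
        ring = (np.hypot(rr - 60, cc - 60) <= 12) & (np.hypot(rr - 60, cc - 60) >= 6)
        img[ring] = 0.9
        found = detect_in_patch(img, params)
        assert not found[10, 10]
        assert found[60, 60]  # ring interior filled before counting
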