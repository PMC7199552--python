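"""1-D k-means on pixel intensities with within/between sum-of-squares.

The clustering step partitions image intensities into dark, medium
(cerebrum), and bright (possible tumor) groups. Lloyd iteration on the
scalar intensities is deterministic here: centroids are seeded at the
(2j-1)/2k intensity quantiles, so no random state is involved.

Cluster quality is summarized by the within-cluster sum of squares

    SSW = sum_i (x_i - c_{k(i)})^2

and the between-cluster sum of squares

    SSB = sum_j n_j (c_j - xbar)^2,

which together decompose the total sum of squares about the overall mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BinaryMask, GrayImage


@dataclass
class ClusterModel:
    """Fitted intensity clustering.

    Attributes
    ----------
    k : number of clusters.
    centroids : cluster centers, sorted ascending (dark first).
    assignment : per-pixel cluster index, same shape as the image.
    n_j : pixel count per cluster.
    overall_centroid : mean intensity of the whole image.
    n_total : total pixel count.
    ssw_history : SSW after each Lloyd iteration (non-increasing).
    """

    k: int
    centroids: np.ndarray
    assignment: np.ndarray
    n_j: np.ndarray
    overall_centroid: float
    n_total: int
    ssw_history: list = field(default_factory=list)


def _quantile_init(x: np.ndarray, k: int) -> np.ndarray:
    """Seed centroids at the (2j-1)/(2k) quantiles, j = 1..k."""
    qs = (2 * np.arange(1, k + 1) - 1) / (2 * k)
    return np.quantile(x, qs)


def kmeans(img: GrayImage, k: int = 3, max_iter: int = 100, tol: float = 1e-4) -> ClusterModel:
    """Lloyd's algorithm on scalar pixel intensities.

    Stops when the largest centroid shift falls below ``tol`` or after
    ``max_iter`` iterations. An emptied cluster is re-seeded at the pixel
    farthest from its current centroid. Centroids are returned sorted
    ascending so index 0 is always the darkest cluster.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    x = img.ravel()
    centroids = np.sort(_quantile_init(x, k))
    ssw_history: list[float] = []
    labels = np.zeros(x.size, dtype=np.intp)
    for _ in range(max_iter):
        d2 = (x[:, None] - centroids[None, :]) ** 2
        labels = np.argmin(d2, axis=1)
        new = centroids.copy()
        for j in range(k):
            sel = labels == j
            if sel.any():
                new[j] = x[sel].mean()
            else:
                # re-seed the empty cluster at the worst-fit pixel
                new[j] = x[np.argmax(np.min(d2, axis=1))]
        new = np.sort(new)
        ssw_history.append(float(np.sum((x - new[np.argmin((x[:, None] - new[None, :]) ** 2, axis=1)]) ** 2)))
        shift = float(np.max(np.abs(new - centroids)))
        centroids = new
        if shift < tol:
            break
    labels = np.argmin((x[:, None] - centroids[None, :]) ** 2, axis=1)
    n_j = np.bincount(labels, minlength=k)
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignment=labels.reshape(img.shape),
        n_j=n_j,
        overall_centroid=float(x.mean()),
        n_total=int(x.size),
        ssw_history=ssw_history,
    )


def ssw(model: ClusterModel, img: GrayImage) -> float:
    """Within-cluster sum of squares of the fitted model on its image."""
    img = np.asarray(img, dtype=np.float64)
    if img.shape != model.assignment.shape:
        raise ValueError("image shape does not match fitted assignment")
    return float(np.sum((img - model.centroids[model.assignment]) ** 2))


def ssb(model: ClusterModel) -> float:
    """Between-cluster sum of squares: sum_j n_j (c_j - xbar)^2."""
    return float(np.sum(model.n_j * (model.centroids - model.overall_centroid) ** 2))


def total_ss(img: GrayImage) -> float:
    """Total sum of squares about the overall mean (equals SSW + SSB)."""
    x = np.asarray(img, dtype=np.float64).ravel()
    return float(np.sum((x - x.mean()) ** 2))


def cluster_masks(model: ClusterModel) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Split a k=3 model into (dark, medium, bright) masks.

    The three masks are pairwise disjoint and cover the image; ordering
    follows the ascending centroid order.
    """
    if model.k != 3:
        raise ValueError(f"cluster_masks requires k=3, model has k={model.k}")
    return (
        model.assignment == 0,
        model.assignment == 1,
        model.assignment == 2,
    )
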