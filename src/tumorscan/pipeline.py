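"""End-to-end detection pipeline and its configuration.

Stages, in order: intensity k-means (k=3) into dark/medium/bright; skull
outline extraction, hole fill and brain-size measurement; inward skull
band; cerebral mask and contrast-focused detection image; shifted
patch-vote scanning of the detection image (and, by default, of the
unmasked focus image so lesions clipped by the cerebral mask still vote);
vote thresholding; candidate labeling; skull-distance evaluation. Nothing
is silently dropped — rejected candidates stay in the report, flagged.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .detect import DetectionParams, _EIGHT
from .evaluate import CandidateRegion, evaluate_candidates
from .io import GrayImage
from .kmeans import cluster_masks, kmeans
from .patches import DEFAULT_SHIFTS, VoteMap, run_passes, select_candidates
from .preprocess import PreprocessConfig, cerebral_mask, focus_image, modified_image
from .skull import DEFAULT_ANCHORS, expand_edge_inward, fill_and_measure, largest_surrounding_edge

log = logging.getLogger("tumorscan")


@dataclass
class PipelineConfig:
    """Every knob of the pipeline, YAML-serializable.

    ``original_pass`` selects the second vote source alongside the masked
    detection image: "focus" (default) votes on the contrast-focused but
    unmasked image, "raw" on the normalized input itself, "none" disables
    the second source.
    """

    kmeans_k: int = 3
    kmeans_tol: float = 1e-4
    kmeans_max_iter: int = 100
    edge_expand_iterations: int = 10
    distance_threshold_anchors: tuple = DEFAULT_ANCHORS
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionParams = field(default_factory=DetectionParams)
    patch_size: int = 200
    scale: int = 3
    shifts: tuple = DEFAULT_SHIFTS
    min_votes: int = 2
    original_pass: str = "focus"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.original_pass not in ("focus", "raw", "none"):
            raise ValueError("original_pass must be 'focus', 'raw', or 'none'")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distance_threshold_anchors"] = [list(a) for a in self.distance_threshold_anchors]
        d["shifts"] = [list(s) for s in self.shifts]
        d["detection"]["thresholds"] = list(self.detection.thresholds)
        d["detection"]["contrast_pass_window"] = list(self.detection.contrast_pass_window)
        d["preprocess"]["narrow_window"] = list(self.preprocess.narrow_window)
        d["preprocess"]["wide_window"] = list(self.preprocess.wide_window)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pre = d.pop("preprocess", {})
        det = d.pop("detection", {})
        if "narrow_window" in pre:
            pre["narrow_window"] = tuple(pre["narrow_window"])
        if "wide_window" in pre:
            pre["wide_window"] = tuple(pre["wide_window"])
        if "thresholds" in det:
            det["thresholds"] = tuple(det["thresholds"])
        if "contrast_pass_window" in det:
            det["contrast_pass_window"] = tuple(det["contrast_pass_window"])
        if "distance_threshold_anchors" in d:
            d["distance_threshold_anchors"] = tuple(tuple(a) for a in d["distance_threshold_anchors"])
        if "shifts" in d:
            d["shifts"] = tuple(tuple(s) for s in d["shifts"])
        return cls(preprocess=PreprocessConfig(**pre), detection=DetectionParams(**det), **d)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    @property
    def digest(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class Region:
    """One reported candidate; bbox is half-open (rmin, cmin, rmax, cmax)."""

    label: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    area: int
    distance_to_skull: float
    accepted: bool


@dataclass
class DetectionReport:
    regions: list
    image_shape: tuple[int, int]
    config_digest: str
    distance_threshold: float = 0.0
    brain_pixels: int = 0
    warnings: list = field(default_factory=list)
    # full-image masks, kept in memory but not serialized
    accepted_mask: np.ndarray | None = None
    candidate_mask: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "image_shape": list(self.image_shape),
            "config_digest": self.config_digest,
            "distance_threshold": self.distance_threshold,
            "brain_pixels": self.brain_pixels,
            "warnings": list(self.warnings),
            "regions": [
                {
                    "label": r.label,
                    "centroid": [float(r.centroid[0]), float(r.centroid[1])],
                    "bbox": [int(b) for b in r.bbox],
                    "area": int(r.area),
                    "distance_to_skull": float(r.distance_to_skull),
                    "accepted": bool(r.accepted),
                }
                for r in self.regions
            ],
        }

    @property
    def accepted_regions(self) -> list:
        return [r for r in self.regions if r.accepted]


def _label_candidates(selected: np.ndarray) -> tuple[np.ndarray, list[CandidateRegion]]:
    labels, n = ndimage.label(selected, structure=_EIGHT)
    cands = []
    for lab in range(1, n + 1):
        mask = labels == lab
        rows, cols = np.nonzero(mask)
        cands.append(
            CandidateRegion(
                mask=mask,
                centroid=(float(rows.mean()), float(cols.mean())),
                area=int(mask.sum()),
            )
        )
    return labels, cands


def detect(img: GrayImage, cfg: PipelineConfig | None = None) -> DetectionReport:
    """Run the full detection pipeline on one normalized slice."""
    cfg = cfg or PipelineConfig()
    img = np.asarray(img, np.float64)
    empty = lambda warn: DetectionReport(
        regions=[],
        image_shape=img.shape,
        config_digest=cfg.digest,
        warnings=[warn],
        accepted_mask=np.zeros(img.shape, bool),
        candidate_mask=np.zeros(img.shape, bool),
    )

    model = kmeans(img, k=cfg.kmeans_k, max_iter=cfg.kmeans_max_iter, tol=cfg.kmeans_tol)
    dark, medium, bright = cluster_masks(model)
    log.info("k-means clusters: dark=%d medium=%d bright=%d px", dark.sum(), medium.sum(), bright.sum())

    try:
        edge = largest_surrounding_edge(bright, medium)
    except ValueError:
        log.warning("no brain found: empty bright+medium union")
        return empty("no-brain-found")
    skull = fill_and_measure(edge, tuple(cfg.distance_threshold_anchors))
    log.info(
        "skull: edge=%d px, brain=%d px, distance threshold=%.2f",
        edge.sum(), skull.brain_pixels, skull.distance_threshold,
    )
    band = expand_edge_inward(skull, cfg.edge_expand_iterations)

    try:
        cereb = cerebral_mask(medium, band)
    except ValueError:
        log.warning("no cerebral tissue found")
        return empty("no-brain-found")
    detection_img = modified_image(img, cereb, cfg.preprocess)
    log.info("cerebral mask: %d px; detection image support: %d px", cereb.sum(), (detection_img > 0).sum())

    vm = run_passes(detection_img, cfg.detection, cfg.shifts, cfg.patch_size, cfg.scale)
    if cfg.original_pass != "none":
        second = focus_image(img, cfg.preprocess) if cfg.original_pass == "focus" else img
        vm2 = run_passes(second, cfg.detection, cfg.shifts, cfg.patch_size, cfg.scale)
        vm = VoteMap(votes=vm.votes + vm2.votes, n_passes=vm.n_passes + vm2.n_passes)
    log.info("vote map: max=%d over %d passes", vm.votes.max(), vm.n_passes)

    selected = select_candidates(vm, min(cfg.min_votes, vm.n_passes))
    labels, cands = _label_candidates(selected)
    log.info("candidates after vote selection: %d", len(cands))

    flagged = evaluate_candidates(cands, skull)
    regions = []
    accepted_mask = np.zeros(img.shape, bool)
    for i, cand in enumerate(flagged, start=1):
        rows, cols = np.nonzero(cand.mask)
        regions.append(
            Region(
                label=i,
                centroid=cand.centroid,
                bbox=(int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1),
                area=cand.area,
                distance_to_skull=cand.min_edge_distance,
                accepted=cand.accepted,
            )
        )
        if cand.accepted:
            accepted_mask |= cand.mask
    log.info("accepted %d of %d candidates", sum(r.accepted for r in regions), len(regions))

    return DetectionReport(
        regions=regions,
        image_shape=img.shape,
        config_digest=cfg.digest,
        distance_threshold=skull.distance_threshold,
        brain_pixels=skull.brain_pixels,
        accepted_mask=accepted_mask,
        candidate_mask=selected,
    )
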