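"""Seeded synthetic brain-slice phantoms with pixel ground truth.

A phantom emulates the gross intensity structure the detector relies on: a
dark background, a bright elliptical skull annulus, a medium-intensity
cerebral interior with additive Gaussian noise, bright tumor disks of
assorted sizes and intensities, and optional skull-adjacent bright decoys
("false tumors") that a correct pipeline must reject by the skull-distance
rule. Disk edges are anti-aliased over one pixel; the ground-truth mask
uses the >= 50% coverage rule and never includes decoys or skull.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class Blob:
    """A rendered disk: center (row, col), radius in px, peak intensity."""

    center: tuple[float, float]
    radius: float
    intensity: float


@dataclass
class PhantomSpec:
    image_size: tuple[int, int] = (512, 512)
    skull_center: tuple[float, float] = (256.0, 256.0)
    skull_semi_axes: tuple[float, float] = (210.0, 180.0)  # (row, col) outer semi-axes
    ring_thickness: float = 6.0
    skull_intensity: float = 0.90
    cerebrum_intensity: float = 0.40
    noise_sigma: float = 0.03
    background_intensity: float = 0.02
    tumors: tuple[Blob, ...] = ()
    decoys: tuple[Blob, ...] = ()
    seed: int = 0
    name: str = "phantom"


@dataclass
class PhantomOutput:
    image: np.ndarray
    truth: np.ndarray
    metadata: dict


def _ellipse_field(shape, center, semi_axes):
    """Normalized squared radius: <= 1 inside the ellipse."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi_axes[0]) ** 2 + ((cc - center[1]) / semi_axes[1]) ** 2


def _disk_coverage(shape, blob: Blob) -> np.ndarray:
    """Per-pixel disk coverage with a 1-px anti-aliased rim."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - blob.center[0], cc - blob.center[1])
    return np.clip(blob.radius + 0.5 - d, 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Render a phantom; bit-identical for identical (spec, seed).

    Raises if a tumor is not strictly inside the cerebral interior, if a
    decoy strays farther than ``ring_thickness + 3`` px from the skull
    ring, or if any disk radius is below 2 px.
    """
    h, w = spec.image_size
    outer = _ellipse_field((h, w), spec.skull_center, spec.skull_semi_axes) <= 1.0
    inner_axes = (
        spec.skull_semi_axes[0] - spec.ring_thickness,
        spec.skull_semi_axes[1] - spec.ring_thickness,
    )
    inner = _ellipse_field((h, w), spec.skull_center, inner_axes) <= 1.0
    ring = outer & ~inner

    rng = np.random.default_rng(spec.seed)
    img = np.full((h, w), spec.background_intensity, dtype=np.float64)
    noise = rng.normal(0.0, spec.noise_sigma, size=(h, w))
    img[inner] = spec.cerebrum_intensity + noise[inner]
    img[ring] = spec.skull_intensity

    truth = np.zeros((h, w), dtype=bool)
    per_tumor_px: list[int] = []
    for blob in spec.tumors + spec.decoys:
        if blob.radius < 2:
            raise ValueError(f"blob radius must be >= 2 px, got {blob.radius}")
    for tumor in spec.tumors:
        cov = _disk_coverage((h, w), tumor)
        footprint = cov > 0
        if not np.all(inner[footprint]):
            raise ValueError(f"tumor at {tumor.center} is not strictly inside the cerebrum")
        img = img * (1 - cov) + tumor.intensity * cov
        disk = cov >= 0.5
        truth |= disk
        per_tumor_px.append(int(disk.sum()))
    if spec.decoys:
        ring_dist = ndimage.distance_transform_edt(~ring)
        for decoy in spec.decoys:
            cov = _disk_coverage((h, w), decoy)
            footprint = cov > 0
            if float(ring_dist[footprint].min()) > spec.ring_thickness + 3:
                raise ValueError(f"decoy at {decoy.center} is too far from the skull ring")
            img = img * (1 - cov) + decoy.intensity * cov

    np.clip(img, 0.0, 1.0, out=img)
    metadata = {
        "name": spec.name,
        "seed": spec.seed,
        "rng": "numpy PCG64 (default_rng)",
        "image_size": list(spec.image_size),
        "n_tumors": len(spec.tumors),
        "n_decoys": len(spec.decoys),
        "tumor_pixels": per_tumor_px,
        "spec": {
            "skull_center": list(spec.skull_center),
            "skull_semi_axes": list(spec.skull_semi_axes),
            "ring_thickness": spec.ring_thickness,
            "skull_intensity": spec.skull_intensity,
            "cerebrum_intensity": spec.cerebrum_intensity,
            "noise_sigma": spec.noise_sigma,
            "background_intensity": spec.background_intensity,
            "tumors": [[*t.center, t.radius, t.intensity] for t in spec.tumors],
            "decoys": [[*d.center, d.radius, d.intensity] for d in spec.decoys],
        },
    }
    return PhantomOutput(image=img, truth=truth, metadata=metadata)


def _suite_specs(seed: int) -> list[PhantomSpec]:
    def sub(i: int) -> int:
        return (1000003 * seed + i) % (2**31 - 1)

    return [
        PhantomSpec(name="large", seed=sub(1), tumors=(Blob((230, 240), 22, 0.90),)),
        PhantomSpec(name="tiny", seed=sub(2), tumors=(Blob((280, 300), 3, 0.90),)),
        PhantomSpec(
            name="mixed8",
            seed=sub(3),
            tumors=(
                Blob((170, 256), 25, 0.95),
                Blob((340, 256), 18, 0.85),
                Blob((256, 150), 14, 0.90),
                Blob((256, 360), 10, 0.80),
                Blob((190, 170), 8, 0.88),
                Blob((190, 340), 6, 0.92),
                Blob((330, 170), 4, 0.90),
                Blob((330, 340), 3, 0.95),
            ),
        ),
        PhantomSpec(
            name="near_edge",
            seed=sub(4),
            tumors=(Blob((100, 256), 8, 0.90), Blob((256, 382), 8, 0.90)),
        ),
        PhantomSpec(
            name="decoys_only",
            seed=sub(5),
            decoys=(
                Blob((256, 424), 5, 0.90),
                Blob((58, 256), 5, 0.90),
                Blob((117, 374), 5, 0.90),
            ),
        ),
        PhantomSpec(name="empty", seed=sub(6)),
        PhantomSpec(
            name="low_contrast",
            seed=sub(7),
            tumors=(Blob((230, 240), 14, 0.55), Blob((300, 310), 8, 0.55)),
        ),
        PhantomSpec(name="straddle", seed=sub(8), tumors=(Blob((256, 200), 10, 0.90),)),
    ]


def default_suite(seed: int = 0) -> list[PhantomOutput]:
    """Fixed battery of 8 phantoms exercising the pipeline's claims.

    Covers one large tumor; one tiny (r=3) tumor; eight mixed-size tumors;
    tumors near (but beyond) the skull-distance threshold; skull-adjacent
    decoys only; an empty brain; low-contrast tumors (0.55 on a 0.40
    cerebrum); and a tumor straddling a default patch boundary.
    """
    return [make_phantom(s) for s in _suite_specs(seed)]
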