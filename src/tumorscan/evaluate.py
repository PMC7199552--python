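"""Skull-distance evaluation of tumor candidates.

Tumors rarely arise directly against the skull, so bright candidates whose
Euclidean distance to the skull outline falls below the brain-size-dependent
threshold are flagged as false tumors. Distance is measured from the
candidate's nearest pixel (not its centroid) via a distance transform of
the edge, so a large lesion is judged by its closest point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import BinaryMask
from .skull import SkullModel


@dataclass
class CandidateRegion:
    mask: BinaryMask
    centroid: tuple[float, float]
    area: int
    min_edge_distance: float = float("nan")
    accepted: bool = False


def min_distance_to_edge(candidate: BinaryMask, edge: BinaryMask) -> float:
    """Minimum Euclidean distance from any candidate pixel to the edge."""
    candidate = np.asarray(candidate, bool)
    edge = np.asarray(edge, bool)
    if candidate.shape != edge.shape:
        raise ValueError("mask shapes differ")
    if not candidate.any() or not edge.any():
        raise ValueError("candidate and edge must both be nonempty")
    dist_to_edge = ndimage.distance_transform_edt(~edge)
    return float(dist_to_edge[candidate].min())


def evaluate_candidates(candidates: list[CandidateRegion], skull: SkullModel) -> list[CandidateRegion]:
    """Flag each candidate by its distance to the skull edge.

    Nothing is dropped: every candidate comes back with
    ``min_edge_distance`` filled in and ``accepted`` set to whether that
    distance clears ``skull.distance_threshold``.
    """
    if not candidates:
        return []
    dist_to_edge = ndimage.distance_transform_edt(~np.asarray(skull.edge, bool))
    out = []
    for cand in candidates:
        d = float(dist_to_edge[np.asarray(cand.mask, bool)].min())
        out.append(
            CandidateRegion(
                mask=cand.mask,
                centroid=cand.centroid,
                area=cand.area,
                min_edge_distance=d,
                accepted=d >= skull.distance_threshold,
            )
        )
    return out
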