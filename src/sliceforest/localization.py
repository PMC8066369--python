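"""Turn lesion masks into human-readable region reports and overlap scores.

Masks produced by the orthogonal-intersection rule are separable, so their
connected components are exactly the Cartesian products of retained runs —
axis-aligned boxes.  Intersections *across* subjects (common regions) need not
be separable, so :func:`region_report` falls back to generic connected
components from scipy.ndimage.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage

from .decision import RunFilterResult
from .volume_io import LesionMask, Volume

__all__ = ["RegionBox", "mask_to_boxes", "region_report", "localization_overlap"]


@dataclass
class RegionBox:
    """An axis-aligned box of suspected lesion voxels.

    ``intervals`` are three half-open index intervals [a0, a1) x [b0, b1) x
    [c0, c1); the centroid is in voxel coordinates.
    """

    intervals: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    voxel_count: int
    centroid: tuple[float, float, float]


def _run_to_interval(run: tuple[int, int]) -> tuple[int, int]:
    start, length = run
    return (start, start + length)


def mask_to_boxes(filtered: tuple[RunFilterResult, RunFilterResult, RunFilterResult]) -> list[RegionBox]:
    """One box per triple in the Cartesian product of runs across directions."""
    boxes = []
    for runs in product(*(f.runs for f in filtered)):
        intervals = tuple(_run_to_interval(r) for r in runs)
        count = 1
        centroid = []
        for a0, a1 in intervals:
            count *= a1 - a0
            centroid.append((a0 + a1 - 1) / 2.0)
        boxes.append(RegionBox(intervals=intervals, voxel_count=count, centroid=tuple(centroid)))  # type: ignore[arg-type]
    return boxes


def region_report(mask: LesionMask, reference: Volume | None = None) -> dict:
    """Summarize a mask: total voxels plus per-component boxes and centroids.

    Components are 6-connected.  When a reference volume is given, each
    centroid is also mapped through its affine to world coordinates.
    """
    labeled, n_components = ndimage.label(mask.data)
    components = []
    for index in range(1, n_components + 1):
        where = labeled == index
        coords = np.argwhere(where)
        lo = coords.min(axis=0)
        hi = coords.max(axis=0) + 1
        centroid = coords.mean(axis=0)
        entry = {
            "bounding_box": [[int(a), int(b)] for a, b in zip(lo, hi)],
            "voxel_count": int(where.sum()),
            "centroid_voxel": [float(c) for c in centroid],
        }
        if reference is not None:
            world = reference.affine @ np.append(centroid, 1.0)
            entry["centroid_world"] = [float(c) for c in world[:3]]
        components.append(entry)
    return {
        "total_voxels": mask.n_voxels,
        "n_components": int(n_components),
        "components": components,
    }


def localization_overlap(pred: LesionMask, truth: LesionMask) -> float:
    """Intersection-over-union of two masks' voxel sets; 1.0 if both empty."""
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    inter = int(np.logical_and(pred.data, truth.data).sum())
    union = int(np.logical_or(pred.data, truth.data).sum())
    if union == 0:
        return 1.0
    return inter / union
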