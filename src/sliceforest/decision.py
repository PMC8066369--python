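"""The k-consecutive-slice rule, orthogonal intersection, and diagnosis.

A suspected lesion shows up as a *run* — a maximal block of consecutive
positive slice predictions — in each of the three slicing directions.  Runs
shorter than the threshold k are treated as classifier noise and zeroed;
surviving runs from the three directions are intersected in 3D as a separable
boolean outer product, mask[a, b, c] = f1[a] * f2[b] * f3[c].  A subject is
diagnosed positive iff that intersection is nonempty, which holds exactly when
every direction retains at least one run of length >= k.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from typing import Sequence

import numpy as np

from .classifier_bank import DecisionVectors
from .volume_io import LesionMask

__all__ = [
    "RunFilterResult",
    "run_filter",
    "intersect_mask",
    "lesion_mask",
    "diagnose",
    "common_region",
]


@dataclass
class RunFilterResult:
    """A binary vector with all runs of 1s shorter than k zeroed.

    ``runs`` lists the retained maximal runs as (start, length) pairs with
    0-based starts; ``filtered[i] == 1`` iff i lies inside some listed run.
    """

    filtered: np.ndarray
    runs: list[tuple[int, int]]


def _as_binary(v) -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("expected a nonempty 1D vector")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("vector entries must be 0 or 1")
    return arr.astype(np.int8)


def run_filter(v, k: int) -> RunFilterResult:
    """Keep only maximal runs of 1s with length >= k.

    k = 1 is the identity (useful for ablation); the published operating
    point is k = 3.
    """
    arr = _as_binary(v)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    padded = np.concatenate(([0], arr, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive
    filtered = np.zeros_like(arr)
    runs: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if e - s >= k:
            filtered[s:e] = 1
            runs.append((int(s), int(e - s)))
    return RunFilterResult(filtered=filtered, runs=runs)


def _filtered_vector(f) -> np.ndarray:
    if isinstance(f, RunFilterResult):
        return f.filtered
    return _as_binary(f)


def intersect_mask(f1, f2, f3) -> LesionMask:
    """Separable boolean outer product of three filtered direction vectors."""
    a, b, c = (_filtered_vector(f) for f in (f1, f2, f3))
    mask = np.einsum("i,j,k->ijk", a, b, c)
    return LesionMask(mask.astype(np.uint8))


def lesion_mask(dv: DecisionVectors, k: int) -> tuple[LesionMask, tuple[RunFilterResult, ...]]:
    """Filter each direction's decision vector, intersect, and return both."""
    filtered = tuple(run_filter(dv.get(d), k) for d in (1, 2, 3))
    return intersect_mask(*filtered), filtered


def diagnose(dv: DecisionVectors, k: int) -> int:
    """1 iff the filtered three-direction intersection is nonempty.

    Equivalently: every direction has at least one run of length >= k.
    """
    mask, _ = lesion_mask(dv, k)
    return int(not mask.is_empty())


def common_region(masks: Sequence[LesionMask]) -> LesionMask:
    """Voxelwise AND across subjects' lesion masks (shared incidence region)."""
    masks = list(masks)
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    for m in masks:
        if m.shape != shape:
            raise ValueError(f"mask shapes differ: {m.shape} vs {shape}")
    data = reduce(np.minimum, (m.data for m in masks))
    return LesionMask(data)
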