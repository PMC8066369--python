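"""Decompose 3D volumes into per-direction, per-position flattened 2D slices.

A volume of shape (D1, D2, D3) yields D1 + D2 + D3 slices: direction d in
{1, 2, 3} slices along axis d-1, and each 2D section is flattened row-major
over the two remaining axes in ascending axis order.  The flattening order is
arbitrary but must be shared between training and prediction; here both go
through :func:`extract_slice`, so the invariant holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Cohort, Volume

__all__ = [
    "SliceVector",
    "DesignMatrix",
    "extract_slice",
    "reconstruct",
    "build_design_matrix",
    "n_positions",
    "slice_length",
]

DIRECTIONS = (1, 2, 3)


@dataclass
class SliceVector:
    direction: int
    position: int
    values: np.ndarray  # flat, length = product of the two remaining dims


@dataclass
class DesignMatrix:
    """Training matrix for one (direction, position) classifier.

    Row i is subject i's flattened slice; labels[i] is subject i's diagnosis
    (every slice of a patient inherits label 1 — the weak-label scheme).
    """

    direction: int
    position: int
    rows: np.ndarray
    labels: np.ndarray


def _check_direction(direction: int) -> int:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be 1, 2 or 3, got {direction}")
    return direction - 1  # axis index


def n_positions(shape: tuple[int, int, int], direction: int) -> int:
    return shape[_check_direction(direction)]


def slice_length(shape: tuple[int, int, int], direction: int) -> int:
    axis = _check_direction(direction)
    out = 1
    for a, s in enumerate(shape):
        if a != axis:
            out *= s
    return out


def _slice_data(data: np.ndarray, direction: int, position: int) -> np.ndarray:
    axis = _check_direction(direction)
    if not 0 <= position < data.shape[axis]:
        raise IndexError(
            f"position {position} out of range for direction {direction} "
            f"(size {data.shape[axis]})"
        )
    return np.take(data, position, axis=axis).ravel()


def extract_slice(volume: Volume, direction: int, position: int) -> SliceVector:
    """The 2D section at ``position`` along ``direction``, flattened."""
    return SliceVector(direction, position, _slice_data(volume.data, direction, position))


def reconstruct(slices: list[SliceVector], shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of slicing one direction: reassemble the 3D grid.

    Requires exactly one slice per position, in consecutive ascending order.
    """
    if not slices:
        raise ValueError("no slices given")
    direction = slices[0].direction
    axis = _check_direction(direction)
    expected = shape[axis]
    positions = [s.position for s in slices]
    if positions != list(range(expected)):
        raise ValueError(
            f"need positions 0..{expected - 1} in order for direction {direction}, "
            f"got {positions}"
        )
    plane_shape = tuple(s for a, s in enumerate(shape) if a != axis)
    planes = []
    for s in slices:
        if s.direction != direction:
            raise ValueError("mixed directions in slice list")
        if s.values.size != plane_shape[0] * plane_shape[1]:
            raise ValueError(
                f"slice at position {s.position} has {s.values.size} values, "
                f"expected {plane_shape[0] * plane_shape[1]}"
            )
        planes.append(np.asarray(s.values).reshape(plane_shape))
    return np.stack(planes, axis=axis)


def build_design_matrix(cohort: Cohort, direction: int, position: int) -> DesignMatrix:
    """Stack one flattened slice per subject, in cohort order, with labels."""
    rows = np.stack([_slice_data(v.data, direction, position) for v in cohort])
    return DesignMatrix(direction, position, rows, cohort.labels)
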