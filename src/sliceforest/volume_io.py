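"""Volume and mask I/O plus the cohort data model.

Volumes are co-registered 3D gray-value grids stored as NIfTI-1 files, one per
subject, with a binary diagnosis label (0 = control, 1 = patient).  The affine
is carried along purely so that exported lesion masks overlay correctly in
standard viewers; classification itself works on raw voxel grids.

Axis convention: axis 0 is direction 1 (cross-section), axis 1 is direction 2
(sagittal), axis 2 is direction 3 (coronal).  All indices are 0-based and
intervals half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Volume",
    "Cohort",
    "LesionMask",
    "read_volume",
    "write_mask",
    "read_cohort",
    "write_manifest",
    "split_folds",
]


@dataclass
class Volume:
    """One subject's 3D gray-value grid with its diagnosis label.

    Parameters
    ----------
    data
        3D array of gray values (arbitrary intensity units).
    subject_id
        Opaque unique identifier.
    label
        0 (control), 1 (patient), or None for unlabeled test volumes.
    affine
        4x4 voxel-to-world matrix, retained for mask export only.
    """

    data: np.ndarray
    subject_id: str
    label: int | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"volume {self.subject_id!r}: expected a 3D grid, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"volume {self.subject_id!r}: non-finite voxel values")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"volume {self.subject_id!r}: label must be 0 or 1, got {self.label}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


class Cohort:
    """An ordered, shape-consistent collection of volumes with unique ids."""

    def __init__(self, volumes: Sequence[Volume]):
        volumes = list(volumes)
        if not volumes:
            raise ValueError("cohort must contain at least one volume")
        shape = volumes[0].shape
        for v in volumes:
            if v.shape != shape:
                raise ValueError(
                    f"volume {v.subject_id!r} has shape {v.shape}, cohort shape is {shape}"
                )
        ids = [v.subject_id for v in volumes]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids are not unique")
        self.volumes: list[Volume] = volumes
        self.shape: tuple[int, int, int] = shape

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self) -> Iterator[Volume]:
        return iter(self.volumes)

    def __getitem__(self, index: int) -> Volume:
        return self.volumes[index]

    @property
    def subject_ids(self) -> list[str]:
        return [v.subject_id for v in self.volumes]

    @property
    def labels(self) -> np.ndarray:
        if any(v.label is None for v in self.volumes):
            raise ValueError("cohort contains unlabeled volumes")
        return np.array([v.label for v in self.volumes], dtype=int)

    def get(self, subject_id: str) -> Volume:
        for v in self.volumes:
            if v.subject_id == subject_id:
                return v
        raise KeyError(subject_id)

    def subset(self, subject_ids: Sequence[str]) -> "Cohort":
        """Sub-cohort in the given id order."""
        return Cohort([self.get(s) for s in subject_ids])

    def validate_for_training(self) -> None:
        labels = self.labels
        if len(np.unique(labels)) < 2:
            raise ValueError("training cohort must contain both classes")


@dataclass
class LesionMask:
    """Binary 3D tensor marking suspected disorder voxels."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.data = arr.astype(np.uint8)

    @classmethod
    def empty(cls, shape: tuple[int, int, int]) -> "LesionMask":
        return cls(np.zeros(shape, dtype=np.uint8))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return not self.data.any()


def read_volume(path: str | Path, label: int | None = None, subject_id: str | None = None) -> Volume:
    """Load a 3D NIfTI-1 volume.

    4D images with a singleton trailing dimension are squeezed; anything else
    non-3D is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: image contains non-finite voxels")
    return Volume(
        data=data,
        subject_id=subject_id if subject_id is not None else path.name.split(".")[0],
        label=label,
        affine=np.asarray(img.affine),
    )


def write_mask(mask: LesionMask, reference: Volume, path: str | Path) -> None:
    """Write a lesion mask as an 8-bit NIfTI-1 file in the reference's space."""
    if mask.shape != reference.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match reference shape {reference.shape}"
        )
    img = nib.Nifti1Image(mask.data.astype(np.uint8), reference.affine)
    nib.save(img, str(path))


def read_cohort(manifest_path: str | Path) -> Cohort:
    """Load a cohort from a two-column CSV manifest (path, label) with header.

    Relative volume paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    if "path" not in table.columns:
        raise ValueError(f"{manifest_path}: manifest needs a 'path' column")
    volumes = []
    for _, row in table.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        label = int(row["label"]) if "label" in table.columns and not pd.isna(row["label"]) else None
        volumes.append(read_volume(p, label=label))
    return Cohort(volumes)


def write_manifest(cohort_paths: Sequence[tuple[str, int]], path: str | Path) -> None:
    pd.DataFrame(cohort_paths, columns=["path", "label"]).to_csv(path, index=False)


def split_folds(
    cohort: Cohort, n_folds: int, seed: int
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Stratified k-fold partition of subject ids.

    Returns one (train_ids, test_ids) pair per fold; the test sets partition the
    cohort, each preserving the class proportions as closely as possible.
    Deterministic given ``seed``.
    """
    if n_folds < 2 or n_folds > len(cohort):
        raise ValueError(f"n_folds must be in [2, {len(cohort)}], got {n_folds}")
    labels = cohort.labels
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs at least {n_folds} members for {n_folds}-fold "
            f"stratified splitting (class counts: {counts.tolist()})"
        )
    ids = np.array(cohort.subject_ids)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        (tuple(ids[train_idx]), tuple(ids[test_idx]))
        for train_idx, test_idx in skf.split(ids, labels)
    ]
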