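"""Phantom cohorts with a planted, class-specific lesion.

The generator emulates the statistical structure the slice-ensemble method
assumes: a cohort of co-registered volumes sharing a common baseline, where
the patient class carries a localized mean-intensity perturbation in one or
two compact axis-aligned boxes.  Each subject's volume is

    baseline + smooth subject jitter + i.i.d. voxel noise + label * lesion,

so with zero noise and jitter every lesion-crossing slice position is
separable by a single voxel threshold.  The "ellipsoid" baseline is a
smoothed, centered soft ellipsoid (intensity 100 inside, 0 outside) that
gives slices brain-like nonstationary structure; "flat" is a constant 100.

This is deliberately not an MRI physics simulator: no bias fields, partial
volume, or morphological deformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .volume_io import Cohort, LesionMask, Volume, write_manifest, write_mask

__all__ = ["PhantomConfig", "PhantomCohort", "generate_cohort", "truth_mask", "write_cohort"]

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

DEFAULT_LESION: Box = ((10, 14), (11, 16), (10, 14))  # 4 x 5 x 4 voxels


@dataclass(frozen=True)
class PhantomConfig:
    """Full specification of a synthetic cohort.

    Defaults describe the reference phantom used throughout the test battery:
    a 24x28x24 grid, 20 controls + 20 patients, one 4x5x4 lesion box, a mean
    shift of 10 intensity units in lesion voxels for patients, voxel noise of
    standard deviation 2 (signal-to-noise 5), no subject jitter.
    """

    shape: tuple[int, int, int] = (24, 28, 24)
    n_controls: int = 20
    n_patients: int = 20
    lesions: tuple[Box, ...] = (DEFAULT_LESION,)
    effect: float = 10.0
    noise_sd: float = 2.0
    baseline: str = "ellipsoid"  # "ellipsoid" | "flat"
    subject_jitter_sd: float = 0.0
    multiplicative: bool = False  # if True, lesion scales voxels by (1 + effect/100)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 1:
            raise ValueError(f"invalid shape {self.shape}")
        if self.n_controls < 1 or self.n_patients < 1:
            raise ValueError("need at least one subject of each class")
        if not self.lesions or len(self.lesions) > 2:
            raise ValueError("configure 1 or 2 lesion boxes")
        for box in self.lesions:
            for axis, (lo, hi) in enumerate(box):
                if not (0 <= lo < hi <= self.shape[axis]):
                    raise ValueError(f"lesion box {box} out of bounds for shape {self.shape}")
        if self.noise_sd < 0 or self.subject_jitter_sd < 0:
            raise ValueError("noise_sd and subject_jitter_sd must be >= 0")
        if self.baseline not in ("ellipsoid", "flat"):
            raise ValueError(f"unknown baseline {self.baseline!r}")


@dataclass
class PhantomCohort:
    cohort: Cohort
    truth_mask: LesionMask
    config: PhantomConfig


def truth_mask(config: PhantomConfig) -> LesionMask:
    """Binary union of the configured lesion boxes."""
    data = np.zeros(config.shape, dtype=np.uint8)
    for (a0, a1), (b0, b1), (c0, c1) in config.lesions:
        data[a0:a1, b0:b1, c0:c1] = 1
    return LesionMask(data)


def _baseline(config: PhantomConfig) -> np.ndarray:
    if config.baseline == "flat":
        return np.full(config.shape, 100.0)
    axes = [np.linspace(-1.0, 1.0, s) if s > 1 else np.zeros(s) for s in config.shape]
    grids = np.meshgrid(*axes, indexing="ij")
    inside = sum((g / 0.8) ** 2 for g in grids) <= 1.0
    return gaussian_filter(inside.astype(float) * 100.0, sigma=1.5)


def _smooth_jitter(rng: np.random.Generator, shape, sd: float) -> np.ndarray:
    """Smooth random field rescaled to unit voxelwise sd, then scaled by sd."""
    fieldv = gaussian_filter(rng.standard_normal(shape), sigma=3.0)
    empirical = fieldv.std()
    if empirical == 0:  # degenerate tiny shapes
        return np.zeros(shape)
    return fieldv * (sd / empirical)


def generate_cohort(config: PhantomConfig) -> PhantomCohort:
    """Simulate a labeled phantom cohort, fully determined by ``config.seed``.

    Subjects come out controls first ("ctrl-000", ...) then patients
    ("pat-000", ...).
    """
    rng = np.random.default_rng(config.seed)
    base = _baseline(config)
    mask = truth_mask(config).data.astype(float)
    volumes = []
    n_total = config.n_controls + config.n_patients
    for i in range(n_total):
        label = 0 if i < config.n_controls else 1
        data = base.copy()
        if config.subject_jitter_sd > 0:
            data += _smooth_jitter(rng, config.shape, config.subject_jitter_sd)
        if config.noise_sd > 0:
            data += rng.normal(0.0, config.noise_sd, config.shape)
        if label == 1:
            if config.multiplicative:
                data *= 1.0 + (config.effect / 100.0) * mask
            else:
                data += config.effect * mask
        sid = f"ctrl-{i:03d}" if label == 0 else f"pat-{i - config.n_controls:03d}"
        volumes.append(Volume(data=data, subject_id=sid, label=label))
    return PhantomCohort(cohort=Cohort(volumes), truth_mask=truth_mask(config), config=config)


def write_cohort(phantom: PhantomCohort, directory: str | Path) -> Path:
    """Write the cohort as NIfTI files + manifest CSV + truth-mask NIfTI.

    Returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for volume in phantom.cohort:
        name = f"{volume.subject_id}.nii.gz"
        nib.save(nib.Nifti1Image(volume.data, volume.affine), str(directory / name))
        entries.append((name, int(volume.label)))
    manifest = directory / "manifest.csv"
    write_manifest(entries, manifest)
    write_mask(phantom.truth_mask, phantom.cohort[0], directory / "truth_mask.nii.gz")
    (directory / "phantom_config.json").write_text(
        json.dumps(asdict(phantom.config), indent=2, default=list)
    )
    return manifest
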