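"""Reading aligned PET volumes and parcellations, global intensity
normalization, and per-ROI voxel-sample extraction.

Volumes are assumed already spatially aligned to the atlas grid; no
registration is performed here. The brain mask is the union of atlas
labels 1..n, and global normalization rescales so the in-mask mean
intensity is exactly 1 (proportional scaling).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .aal import default_region_names

__all__ = [
    "Volume",
    "AtlasLabels",
    "ROISampleSet",
    "read_volume",
    "write_volume",
    "read_atlas",
    "global_normalize",
    "extract_roi_samples",
    "read_subject_table",
]


@dataclass
class Volume:
    """A 3D scalar intensity grid with its grid-to-world transform."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(f"non-finite voxel at index {tuple(int(v) for v in bad)}")

    @property
    def voxel_dims(self) -> np.ndarray:
        """Physical voxel spacing in mm, from the affine."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class AtlasLabels:
    """Integer-labeled parcellation: 0 = background, 1..n = regions."""

    labels: np.ndarray
    region_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = np.rint(self.labels).astype(np.int64)
            if not np.allclose(self.labels, as_int):
                raise ValueError("atlas labels must be integers")
            self.labels = as_int
        n = len(self.region_names)
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() > n:
            raise ValueError(
                f"label values must lie in 0..{n}, found range "
                f"[{present.min()}, {present.max()}]"
            )
        counts = np.bincount(self.labels.ravel(), minlength=n + 1)
        for region in range(1, n + 1):
            if counts[region] < 2:
                raise ValueError(
                    f"region {region} ({self.region_names[region - 1]}) has "
                    f"{counts[region]} voxels; at least 2 required"
                )

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def voxel_counts(self) -> np.ndarray:
        """Number of voxels per region, index 0 = region 1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_regions + 1)[1:]

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class ROISampleSet:
    """Per-subject normalized voxel-intensity samples, one vector per region."""

    subject_id: str
    samples: list[np.ndarray]
    group: Optional[str] = None
    region_names: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.samples = [np.asarray(s, dtype=np.float64) for s in self.samples]
        if self.region_names is None:
            self.region_names = default_region_names(len(self.samples))
        if len(self.samples) != len(self.region_names):
            raise ValueError("one sample vector per region required")
        for i, s in enumerate(self.samples):
            if s.size == 0:
                raise ValueError(f"region {i + 1} has no samples")
            if not np.all(np.isfinite(s)):
                raise ValueError(f"region {i + 1} has non-finite samples")
        if self.group is not None and self.group not in ("SZF", "SZR"):
            raise ValueError(f"group must be 'SZF' or 'SZR', got {self.group!r}")

    @property
    def n_regions(self) -> int:
        return len(self.samples)


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) volume; non-finite voxels are rejected."""
    img = nib.load(os.fspath(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    return Volume(data=data, affine=np.asarray(img.affine))


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    nib.save(nib.Nifti1Image(volume.data, volume.affine), os.fspath(path))


def read_atlas(
    path: str | os.PathLike, region_names: Optional[Sequence[str]] = None
) -> AtlasLabels:
    """Read an integer parcellation volume.

    ``region_names`` defaults to the AAL-90 abbreviations when the atlas
    holds 90 regions.
    """
    img = nib.load(os.fspath(path))
    labels = np.rint(np.asarray(img.dataobj)).astype(np.int64)
    if region_names is None:
        region_names = default_region_names(int(labels.max()))
    return AtlasLabels(labels=labels, region_names=list(region_names))


def read_region_names(path: str | os.PathLike) -> list[str]:
    """Read a two-column TSV (label, name) into a label-ordered name list."""
    table = pd.read_csv(path, sep="\t", header=None, names=["label", "name"])
    table = table.sort_values("label")
    expected = np.arange(1, len(table) + 1)
    if not np.array_equal(table["label"].to_numpy(), expected):
        raise ValueError("region-name table labels must be consecutive from 1")
    return table["name"].astype(str).tolist()


def global_normalize(volume: Volume, mask: np.ndarray) -> Volume:
    """Proportionally scale so the in-mask mean intensity equals 1.

    Out-of-mask voxels are zeroed. Idempotent: normalizing twice gives
    the same result as once.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.data.shape:
        raise ValueError("mask shape must match volume shape")
    if not mask.any():
        raise ValueError("empty brain mask")
    grand_mean = float(volume.data[mask].mean())
    if grand_mean <= 0:
        raise ValueError(f"non-positive in-mask grand mean ({grand_mean})")
    out = np.zeros_like(volume.data)
    out[mask] = volume.data[mask] / grand_mean
    return Volume(data=out, affine=volume.affine)


def extract_roi_samples(
    volume: Volume,
    atlas: AtlasLabels,
    subject_id: str = "subject",
    group: Optional[str] = None,
) -> ROISampleSet:
    """Collect each region's voxel intensities in raster-scan order.

    ``samples[i]`` holds exactly the intensities of voxels labeled
    ``i + 1``, traversed in C order so sample vectors are reproducible.
    """
    if volume.data.shape != atlas.labels.shape:
        raise ValueError(
            f"volume shape {volume.data.shape} does not match "
            f"atlas shape {atlas.labels.shape}"
        )
    flat_labels = atlas.labels.ravel(order="C")
    flat_data = volume.data.ravel(order="C")
    samples = []
    for region in range(1, atlas.n_regions + 1):
        vals = flat_data[flat_labels == region]
        if vals.size < 2:
            raise ValueError(f"region {region} has {vals.size} voxels; need >= 2")
        samples.append(vals)
    return ROISampleSet(
        subject_id=subject_id,
        samples=samples,
        group=group,
        region_names=list(atlas.region_names),
    )


def read_subject_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read the cohort manifest CSV (subject_id, pet_path, group)."""
    table = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "pet_path", "group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    bad = set(table["group"].dropna()) - {"SZF", "SZR"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    return table
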