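"""Seeded synthetic cohorts for exercising the full pipeline.

The generator emulates per-ROI voxel-intensity samples for two outcome
groups (SZF / SZR). Each region r has a cohort-level baseline mean
mu_r; each subject adds a global offset (between-subject variation of
the kind global normalization removes); voxels are Gaussian around the
subject's regional mean. Group differences are injected into chosen
region pairs: for an effect pair (i, j) the two regions share a
baseline mean, and in group SZR region j is shifted by
``effect_size * noise_sd``, which lowers that pair's Jensen-Shannon
similarity in SZR relative to SZF.

Two modes produce identical data: direct ROI-sample mode, and a
phantom-NIfTI mode that writes the same samples into cuboid regions of
a label volume so the image pathway (read, normalize, extract) can be
tested end to end.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .aal import default_region_names
from .parcellation import AtlasLabels, ROISampleSet, Volume, write_volume

__all__ = [
    "SimulationConfig",
    "choose_effect_pairs",
    "simulate_cohort",
    "simulate_phantom",
    "make_null_cohort",
    "write_phantom_cohort",
]

#: Subject-level global offset SD, as a fraction of noise_sd.
SUBJECT_OFFSET_FRACTION = 0.5

#: Baseline regional means are drawn uniformly from this range
#: (normalized-intensity units, centered on the global mean of 1).
BASELINE_MEAN_RANGE = (0.8, 1.2)


@dataclass
class SimulationConfig:
    """Cohort-generation parameters.

    ``effect_size`` (delta) is the SZR shift of each effect pair's
    target region in units of ``noise_sd``.
    """

    n_per_group: int = 20
    n_vox: int = 200
    n_regions: int = 90
    effect_pairs: list[tuple[int, int]] = field(default_factory=list)
    effect_size: float = 3.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_vox < 10:
            raise ValueError("n_vox must be >= 10")
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for i, j in self.effect_pairs:
            if not (0 <= i < self.n_regions and 0 <= j < self.n_regions):
                raise ValueError(f"effect pair ({i}, {j}) out of range")
            if i == j:
                raise ValueError("effect pair regions must differ")


def choose_effect_pairs(
    n_regions: int, n_pairs: int, seed: int = 0
) -> list[tuple[int, int]]:
    """Disjoint random region pairs (each region in at most one pair)."""
    if 2 * n_pairs > n_regions:
        raise ValueError("not enough regions for disjoint pairs")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_regions)
    return [tuple(sorted((int(perm[2 * k]), int(perm[2 * k + 1]))))
            for k in range(n_pairs)]


def _regional_means(config: SimulationConfig, rng: np.random.Generator):
    lo, hi = BASELINE_MEAN_RANGE
    mu = rng.uniform(lo, hi, size=config.n_regions)
    for i, j in config.effect_pairs:
        mu[j] = mu[i]  # shared baseline so the pair is similar under SZF
    return mu


def simulate_cohort(config: SimulationConfig) -> list[ROISampleSet]:
    """Generate the two-group cohort in direct ROI-sample mode.

    Subjects are ordered SZF first then SZR; everything is drawn from a
    single generator seeded by ``config.seed``, so cohorts are
    bit-identical across runs with the same config.
    """
    rng = np.random.default_rng(config.seed)
    mu = _regional_means(config, rng)
    names = default_region_names(config.n_regions)
    shift = config.effect_size * config.noise_sd
    cohort: list[ROISampleSet] = []
    for group in ("SZF", "SZR"):
        for k in range(config.n_per_group):
            offset = rng.normal(0.0, SUBJECT_OFFSET_FRACTION * config.noise_sd)
            means = mu + offset
            if group == "SZR":
                for _, j in config.effect_pairs:
                    means[j] = means[j] + shift
            samples = [
                rng.normal(means[r], config.noise_sd, size=config.n_vox)
                for r in range(config.n_regions)
            ]
            cohort.append(ROISampleSet(
                subject_id=f"sub-{group}{k + 1:03d}",
                samples=samples,
                group=group,
                region_names=names,
            ))
    return cohort


def make_null_cohort(config: SimulationConfig) -> list[ROISampleSet]:
    """Same cohort with group labels randomly permuted (seeded).

    Label counts are preserved; marginal data are untouched. Used to
    calibrate the classifier against chance.
    """
    cohort = simulate_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    labels = [s.group for s in cohort]
    perm = rng.permutation(len(cohort))
    return [
        ROISampleSet(
            subject_id=s.subject_id,
            samples=s.samples,
            group=labels[perm[k]],
            region_names=s.region_names,
        )
        for k, s in enumerate(cohort)
    ]


def _phantom_layout(config: SimulationConfig,
                    grid_shape: Optional[tuple[int, int, int]]):
    """Cuboid block layout: lattice of blocks separated by background."""
    side = int(np.ceil(config.n_vox ** (1 / 3)))
    gx = int(np.ceil(config.n_regions ** (1 / 3)))
    gy = int(np.ceil(np.sqrt(config.n_regions / gx)))
    gz = int(np.ceil(config.n_regions / (gx * gy)))
    cell = side + 1  # one-voxel background gap between blocks
    needed = (gx * cell + 1, gy * cell + 1, gz * cell + 1)
    if grid_shape is None:
        grid_shape = needed
    if any(g < n for g, n in zip(grid_shape, needed)):
        raise ValueError(
            f"grid {grid_shape} too small; need at least {needed} for "
            f"{config.n_regions} regions of {config.n_vox} voxels"
        )
    labels = np.zeros(grid_shape, dtype=np.int64)
    region = 1
    for ix in range(gx):
        for iy in range(gy):
            for iz in range(gz):
                if region > config.n_regions:
                    break
                x0, y0, z0 = 1 + ix * cell, 1 + iy * cell, 1 + iz * cell
                block = np.zeros(grid_shape, dtype=bool)
                block[x0:x0 + side, y0:y0 + side, z0:z0 + side] = True
                flat = np.flatnonzero(block.ravel())[: config.n_vox]
                labels.ravel()[flat] = region
                region += 1
    return labels


def simulate_phantom(
    config: SimulationConfig,
    grid_shape: Optional[tuple[int, int, int]] = None,
) -> tuple[AtlasLabels, list[tuple[Volume, str, str]]]:
    """Phantom-NIfTI mode: the direct-mode cohort written into volumes.

    Returns the shared atlas and, per subject, (volume, group,
    subject_id). Each region's samples occupy its labeled voxels in
    raster-scan order, so extraction reproduces the direct-mode sample
    vectors exactly.
    """
    labels = _phantom_layout(config, grid_shape)
    atlas = AtlasLabels(labels=labels,
                        region_names=default_region_names(config.n_regions))
    cohort = simulate_cohort(config)
    flat_idx = {
        r: np.flatnonzero(labels.ravel() == r)
        for r in range(1, config.n_regions + 1)
    }
    volumes = []
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    for subject in cohort:
        data = np.zeros(labels.shape, dtype=np.float64)
        flat = data.ravel()
        for r in range(1, config.n_regions + 1):
            flat[flat_idx[r]] = subject.samples[r - 1]
        volumes.append((Volume(data=data, affine=affine),
                        subject.group, subject.subject_id))
    return atlas, volumes


def write_phantom_cohort(
    config: SimulationConfig,
    out_dir: str | os.PathLike,
    grid_shape: Optional[tuple[int, int, int]] = None,
) -> pd.DataFrame:
    """Write atlas + per-subject NIfTI volumes + manifest CSV to disk.

    Returns the manifest (subject_id, pet_path, group, seed); the atlas
    is ``atlas.nii.gz`` next to the volumes.
    """
    import nibabel as nib

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    atlas, volumes = simulate_phantom(config, grid_shape)
    atlas_path = os.path.join(out_dir, "atlas.nii.gz")
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), np.diag([2.0, 2.0, 2.0, 1.0])),
             atlas_path)
    rows = []
    for volume, group, subject_id in volumes:
        path = os.path.join(out_dir, f"{subject_id}.nii.gz")
        write_volume(volume, path)
        rows.append({"subject_id": subject_id, "pet_path": path,
                     "group": group, "seed": config.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
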