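"""Voxelised volume containers: activity images, attenuation maps, atlases."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import GridSpec

__all__ = ["VoxelImage", "MuMap", "BrainAtlas", "SOFT_TISSUE_MU", "BRAIN_REGIONS"]

#: linear attenuation coefficient of soft tissue at 511 keV, cm^-1
SOFT_TISSUE_MU = 0.097

#: the five quantified brain regions (label -> name); 0 is background
BRAIN_REGIONS = {1: "cortex", 2: "caudate putamen", 3: "thalamus",
                 4: "hippocampus", 5: "cerebellum"}


@dataclass
class VoxelImage:
    """A scalar volume on a :class:`GridSpec`.

    ``values`` is activity concentration in kBq/cm^3 for emission phantoms,
    or unitless reconstructed intensity.
    """

    grid: GridSpec
    values: np.ndarray
    is_activity: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(f"values shape {self.values.shape} != grid {self.grid.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if self.is_activity and np.any(self.values < 0):
            raise ValueError("activity images must be nonnegative")

    def copy(self) -> "VoxelImage":
        return VoxelImage(self.grid, self.values.copy(), self.is_activity)

    def total_activity_kbq(self) -> float:
        """Sum of value * voxel volume; only meaningful for activity images."""
        return float(self.values.sum() * self.grid.voxel_volume_cm3)


@dataclass
class MuMap:
    """511-keV linear attenuation coefficients, cm^-1 per voxel."""

    grid: GridSpec
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        if self.mu.shape != tuple(self.grid.shape):
            raise ValueError("mu shape does not match grid")
        if np.any(self.mu < 0) or not np.all(np.isfinite(self.mu)):
            raise ValueError("mu must be finite and nonnegative")


@dataclass
class BrainAtlas:
    """Integer region labels on a grid.  Label 0 is background; every voxel
    carries exactly one label, and each named region must be nonempty."""

    grid: GridSpec
    labels: np.ndarray
    region_names: dict[int, str] = field(default_factory=lambda: dict(BRAIN_REGIONS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.shape != tuple(self.grid.shape):
            raise ValueError("labels shape does not match grid")
        present = set(np.unique(self.labels).tolist())
        missing = [name for lab, name in self.region_names.items() if lab not in present]
        if missing:
            raise ValueError(f"empty atlas regions: {missing}")

    def region_mask(self, region: int | str) -> np.ndarray:
        if isinstance(region, str):
            by_name = {v: k for k, v in self.region_names.items()}
            region = by_name[region]
        return self.labels == region

    @property
    def names(self) -> list[str]:
        return [self.region_names[k] for k in sorted(self.region_names)]
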