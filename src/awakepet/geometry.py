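"""Scanner and voxel-grid geometry.

World coordinates are millimetres in the scanner frame: the z axis is the
scanner (bore) axis, x/y span the transaxial plane, and the origin sits at
the centre of the field of view.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["ScannerGeometry", "GridSpec", "desk_scanner", "inveon_like_scanner",
           "desk_head_grid", "paper_matrix_grid"]


@dataclass(frozen=True)
class ScannerGeometry:
    """Cylindrical PET scanner: rings of crystals on a cylinder.

    Crystals are indexed ``ring * n_crystals_per_ring + i`` with ``i``
    counting counter-clockwise from the +x axis.  Crystal centres lie
    exactly on the cylinder of radius ``ring_radius``.
    """

    ring_radius: float            # mm
    n_crystals_per_ring: int
    n_rings: int
    crystal_axial_pitch: float    # mm, ring-to-ring spacing
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")
        if self.n_crystals_per_ring < 8 or self.n_crystals_per_ring % 2:
            raise ValueError("n_crystals_per_ring must be even and >= 8")
        if self.n_rings < 1 or self.crystal_axial_pitch <= 0:
            raise ValueError("need n_rings >= 1 and positive axial pitch")

    @property
    def axial_fov(self) -> float:
        """Axial extent covered by the rings, mm."""
        return self.n_rings * self.crystal_axial_pitch

    @property
    def n_crystals(self) -> int:
        return self.n_rings * self.n_crystals_per_ring

    @cached_property
    def crystal_positions(self) -> np.ndarray:
        """(n_crystals, 3) array of crystal-centre coordinates, mm."""
        i = np.arange(self.n_crystals_per_ring)
        phi = 2.0 * np.pi * i / self.n_crystals_per_ring
        xy = self.ring_radius * np.stack([np.cos(phi), np.sin(phi)], axis=1)
        z0 = -0.5 * self.axial_fov
        pos = np.empty((self.n_crystals, 3))
        for r in range(self.n_rings):
            sl = slice(r * self.n_crystals_per_ring, (r + 1) * self.n_crystals_per_ring)
            pos[sl, :2] = xy
            pos[sl, 2] = z0 + (r + 0.5) * self.crystal_axial_pitch
        pos.setflags(write=False)
        return pos

    def crystal_position(self, index: int) -> np.ndarray:
        return self.crystal_positions[index]

    def crystal_index(self, ring: np.ndarray, transaxial: np.ndarray) -> np.ndarray:
        return ring * self.n_crystals_per_ring + transaxial


def desk_scanner() -> ScannerGeometry:
    """Small default geometry sized for quick desk-scale simulation.

    The crystal pitch (1.6 mm transaxial, 2 mm axial) is kept close to a
    real small-animal scanner's: coarser pitches alias the discrete LOR
    set on the reconstruction grid, which biases regional means in
    static-vs-moving comparisons.
    """
    return ScannerGeometry(ring_radius=50.0, n_crystals_per_ring=192,
                           n_rings=16, crystal_axial_pitch=2.0, name="desk")


def inveon_like_scanner() -> ScannerGeometry:
    """Preset emulating a small-animal scanner with a 10 cm transaxial
    diameter and a 12.7 cm axial field of view."""
    return ScannerGeometry(ring_radius=50.0, n_crystals_per_ring=160,
                           n_rings=64, crystal_axial_pitch=127.0 / 64,
                           name="inveon-like")


@dataclass(frozen=True)
class GridSpec:
    """Regular voxel grid.  ``origin`` is the world coordinate (mm) of the
    corner of voxel (0, 0, 0); the centre of voxel ``i`` is at
    ``origin + (i + 0.5) * voxel_size``."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @classmethod
    def centered(cls, shape, voxel_size) -> "GridSpec":
        shape = tuple(int(s) for s in shape)
        voxel_size = tuple(float(v) for v in voxel_size)
        origin = tuple(-s * v / 2.0 for s, v in zip(shape, voxel_size))
        return cls(shape, voxel_size, origin)

    @property
    def voxel_volume_mm3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def extent(self) -> np.ndarray:
        """(2, 3) array of [low corner; high corner] in mm."""
        o = np.asarray(self.origin)
        return np.stack([o, o + np.asarray(self.shape) * np.asarray(self.voxel_size)])

    def voxel_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel_size[axis]

    def center_of(self, index: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centres for integer index array (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + (idx + 0.5) * np.asarray(self.voxel_size)

    def index_of(self, world: np.ndarray) -> np.ndarray:
        """Integer voxel index containing the world point(s); may be out of range."""
        w = np.asarray(world, dtype=float)
        return np.floor((w - np.asarray(self.origin)) / np.asarray(self.voxel_size)).astype(np.int64)

    def contains(self, world: np.ndarray) -> np.ndarray:
        idx = self.index_of(world)
        sh = np.asarray(self.shape)
        return np.all((idx >= 0) & (idx < sh), axis=-1)


def desk_head_grid() -> GridSpec:
    """Default head-frame reconstruction grid: 64 x 64 x 24 at 1 mm,
    centred, tall enough to hold the brain and the elevated marker."""
    return GridSpec.centered((64, 64, 24), (1.0, 1.0, 1.0))


def paper_matrix_grid() -> GridSpec:
    """Full-scanner reconstruction matrix preset: 128 x 128 x 159 voxels of
    0.776 x 0.776 x 0.796 mm."""
    return GridSpec.centered((128, 128, 159), (0.776, 0.776, 0.796))
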