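"""Digital mouse-head phantom.

The phantom is a soft-tissue ellipsoid ("body", here the head/neck tissue)
containing an ellipsoidal brain partitioned into the five quantified
regions: cortex, caudate putamen, thalamus, hippocampus and cerebellum.
Region geometry is schematic — each region is a simple solid placed
roughly where it belongs — because downstream code only needs disjoint,
nonempty labelled regions with known activities, not anatomical fidelity.

Conventions: +y is anterior (nose), +z dorsal (up).  Activities are
kBq/cm^3 and constant within each region.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GridSpec
from .volumes import BRAIN_REGIONS, SOFT_TISSUE_MU, BrainAtlas, MuMap, VoxelImage

__all__ = ["EllipsoidSpec", "make_head_phantom", "DEFAULT_REGION_ACTIVITIES",
           "default_body"]

#: default region activity concentrations, kBq/cm^3, loosely mimicking the
#: regional FDG uptake ordering and magnitude in mouse brain after an
#: ~18.5 MBq injection (SUV ~2-3 at ~25 g body weight; thalamus hottest).
DEFAULT_REGION_ACTIVITIES = {
    "cortex": 1500.0,
    "caudate putamen": 1800.0,
    "thalamus": 2000.0,
    "hippocampus": 1700.0,
    "cerebellum": 1600.0,
    "body": 400.0,
}


@dataclass(frozen=True)
class EllipsoidSpec:
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("ellipsoid semi-axes must be positive")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        u = (np.asarray(pts) - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.sum(u * u, axis=-1) <= 1.0


def default_body() -> EllipsoidSpec:
    """Head/neck soft-tissue outline enclosing the brain."""
    return EllipsoidSpec(center=(0.0, 0.0, 0.0), semi_axes=(12.0, 16.0, 9.0))


_BRAIN = EllipsoidSpec(center=(0.0, 1.0, 1.0), semi_axes=(5.5, 7.5, 4.5))


def _brain_labels(grid: GridSpec, brain: EllipsoidSpec) -> np.ndarray:
    """Partition the brain ellipsoid into the 5 regions (priority order:
    cerebellum, thalamus, caudate putamen, hippocampus; remainder cortex)."""
    xs = [grid.voxel_centers(a) for a in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    cx, cy, cz = brain.center
    lx, ly, lz = X - cx, Y - cy, Z - cz     # brain-local mm

    in_brain = brain.contains(pts)
    labels = np.zeros(grid.shape, dtype=np.int16)
    name_to_label = {v: k for k, v in BRAIN_REGIONS.items()}

    cerebellum = in_brain & (ly < -4.2)
    thalamus = in_brain & (((lx / 2.4) ** 2 + ((ly + 0.5) / 2.4) ** 2
                            + ((lz + 0.5) / 2.0) ** 2) <= 1.0) & ~cerebellum
    caudate = in_brain & ~cerebellum & ~thalamus & (
        ((np.abs(lx) - 2.6) ** 2 + (ly - 3.0) ** 2 + (lz + 0.5) ** 2) <= 1.9 ** 2)
    hippocampus = in_brain & ~cerebellum & ~thalamus & ~caudate & (
        (ly >= -4.2) & (ly <= -0.8) & (np.abs(lx) <= 4.0) & (np.abs(lz) <= 2.6))
    cortex = in_brain & ~cerebellum & ~thalamus & ~caudate & ~hippocampus

    labels[cortex] = name_to_label["cortex"]
    labels[caudate] = name_to_label["caudate putamen"]
    labels[thalamus] = name_to_label["thalamus"]
    labels[hippocampus] = name_to_label["hippocampus"]
    labels[cerebellum] = name_to_label["cerebellum"]
    return labels


def make_head_phantom(grid: GridSpec,
                      region_activities: dict[str, float] | None = None,
                      body: EllipsoidSpec | None = None,
                      brain: EllipsoidSpec | None = None,
                      ) -> tuple[VoxelImage, MuMap, BrainAtlas]:
    """Build (activity image, attenuation map, atlas) on ``grid``.

    ``region_activities`` maps the five region names (plus optional
    ``"body"`` for non-brain tissue) to kBq/cm^3.  The attenuation map is
    0.097 cm^-1 inside the body ellipsoid and 0 outside.
    """
    acts = dict(DEFAULT_REGION_ACTIVITIES)
    if region_activities is not None:
        acts.update(region_activities)
    for name, a in acts.items():
        if a < 0:
            raise ValueError(f"negative activity for region {name!r}")
    missing = [n for n in BRAIN_REGIONS.values() if n not in acts]
    if missing:
        raise ValueError(f"missing region activities: {missing}")

    body = body or default_body()
    brain = brain or _BRAIN
    # brain must sit inside the body outline: check the axis extreme points
    center = np.array(brain.center)
    extremes = np.concatenate([center + np.diag(brain.semi_axes),
                               center - np.diag(brain.semi_axes)])
    if not np.all(body.contains(extremes)):
        raise ValueError("brain ellipsoid is not enclosed by the body outline")

    labels = _brain_labels(grid, brain)
    atlas = BrainAtlas(grid, labels)

    xs = [grid.voxel_centers(a) for a in range(3)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    pts = np.stack([X, Y, Z], axis=-1)
    in_body = body.contains(pts)

    values = np.zeros(grid.shape)
    values[in_body] = float(acts.get("body", 0.0))
    for lab, name in BRAIN_REGIONS.items():
        values[labels == lab] = float(acts[name])

    mu = np.where(in_body, SOFT_TISSUE_MU, 0.0)
    return (VoxelImage(grid, values, is_activity=True),
            MuMap(grid, mu), atlas)
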