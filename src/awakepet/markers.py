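"""Fiducial point-source marker model.

Four ~1-mm radioactive point sources are glued to the head: one under each
ear, one on the nasal bridge, and one elevated on a lightweight spacer.
The four points form an asymmetric, non-coplanar tetrahedron whose six
pairwise distances are all distinct, so that matching detected candidates
to the model by inter-point distances has a unique ordering.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["MarkerModel", "default_marker_model", "MARKER_ACTIVITY_RANGE_KBQ"]

#: per-source activity range, kBq
MARKER_ACTIVITY_RANGE_KBQ = (296.0, 370.0)

_PAIRS = list(combinations(range(4), 2))


@dataclass
class MarkerModel:
    """Reference coordinates (mm, head frame) and activities of the four
    point sources."""

    points: np.ndarray                      # (4, 3) mm
    activities_kbq: np.ndarray              # (4,) kBq
    diameter_mm: float = 1.0
    activity_range_kbq: tuple[float, float] = MARKER_ACTIVITY_RANGE_KBQ

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.activities_kbq = np.asarray(self.activities_kbq, dtype=np.float64)
        if self.points.shape != (4, 3):
            raise ValueError("marker model requires exactly 4 three-dimensional points")
        if self.activities_kbq.shape != (4,):
            raise ValueError("need one activity per marker")
        lo, hi = self.activity_range_kbq
        if np.any(self.activities_kbq < lo) or np.any(self.activities_kbq > hi):
            raise ValueError(f"marker activities must lie in [{lo}, {hi}] kBq")
        if self.diameter_mm <= 0:
            raise ValueError("marker diameter must be positive")
        sv = np.linalg.svd(self.points - self.points.mean(axis=0), compute_uv=False)
        if sv[-1] < 1e-3:
            raise ValueError("marker points are (near-)coplanar; pose fitting is degenerate")

    @property
    def pair_distances(self) -> np.ndarray:
        """The 6 pairwise distances (mm), in (i<j) lexicographic pair order."""
        return np.array([np.linalg.norm(self.points[i] - self.points[j])
                         for i, j in _PAIRS])

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def total_activity_kbq(self) -> float:
        return float(self.activities_kbq.sum())

    def validate_distinct_distances(self, margin_mm: float = 0.5) -> None:
        """Raise unless all six pairwise distances differ by >= ``margin_mm``
        — the asymmetry the distance-based matcher relies on."""
        d = np.sort(self.pair_distances)
        gap = float(np.diff(d).min())
        if gap < margin_mm:
            raise ValueError(
                f"marker pairwise distances too similar (min gap {gap:.3f} mm "
                f"< {margin_mm} mm); distance matching may be ambiguous")


def default_marker_model(seed: int | None = None) -> MarkerModel:
    """Default mouse-head layout: two ear markers, nasal bridge, elevated
    spacer marker.  Activities are drawn uniformly from the allowed range
    (fixed midpoints if ``seed`` is None)."""
    points = np.array([
        [-10.20, -5.98, -1.20],   # under left ear, on the head surface
        [10.15, -4.72, -1.53],    # under right ear
        [0.54, 15.25, 2.07],      # nasal bridge
        [0.81, 5.08, 9.51],       # above the head, on spacer
    ])
    lo, hi = MARKER_ACTIVITY_RANGE_KBQ
    if seed is None:
        acts = np.full(4, 0.5 * (lo + hi))
    else:
        acts = np.random.default_rng(seed).uniform(lo, hi, size=4)
    model = MarkerModel(points=points, activities_kbq=acts)
    model.validate_distinct_distances(0.5)
    return model
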