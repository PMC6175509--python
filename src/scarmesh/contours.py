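"""Per-slice endo/epicardial contours.

Contours are ordered 2D polygons delineated on short-axis slices, one
polygon per (surface, slice) pair. In-plane coordinates are world mm;
the slice index refers to the third (z) axis of the reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SURFACE_LABELS = ("lv_endo", "lv_epi", "rv_endo", "rv_epi")


def polygon_signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of an ordered 2D polygon (positive = CCW)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_is_simple(points: np.ndarray) -> bool:
    """True if the closed polygon has no self-intersections."""
    from shapely.geometry import Polygon

    return Polygon(np.asarray(points, dtype=float)).is_valid


@dataclass
class Contour:
    """One ordered polygon on one slice for one anatomical surface."""

    surface: str
    slice_index: int
    points: np.ndarray  # (N, 2) in-plane mm

    def __post_init__(self) -> None:
        if self.surface not in SURFACE_LABELS:
            raise ValueError(
                f"unknown surface label {self.surface!r}; expected one of {SURFACE_LABELS}"
            )
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be an (N, 2) array")
        if len(self.points) < 3:
            raise ValueError(
                f"polygon needs >= 3 points, got {len(self.points)} "
                f"({self.surface}, slice {self.slice_index})"
            )
        self.slice_index = int(self.slice_index)


@dataclass
class ContourSet:
    """All contours of a study, across slices and surfaces."""

    contours: list[Contour] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)

    def add(self, surface: str, slice_index: int, points: np.ndarray) -> None:
        self.contours.append(Contour(surface, slice_index, points))

    def surfaces(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.contours:
            seen.setdefault(c.surface, None)
        return list(seen)

    def for_surface(self, surface: str) -> list[Contour]:
        return [c for c in self.contours if c.surface == surface]

    def slices(self, surface: str | None = None) -> list[int]:
        sel = self.contours if surface is None else self.for_surface(surface)
        return sorted({c.slice_index for c in sel})

    def get(self, surface: str, slice_index: int) -> Contour | None:
        for c in self.contours:
            if c.surface == surface and c.slice_index == slice_index:
                return c
        return None

    def validate_simple(self) -> None:
        """Raise if any polygon self-intersects."""
        for c in self.contours:
            if not polygon_is_simple(c.points):
                raise ValueError(
                    f"polygon for ({c.surface}, slice {c.slice_index}) is not simple"
                )
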