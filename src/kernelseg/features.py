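"""Morphological descriptors of separated kernels.

Eight features per kernel drive the damage classifier:

- area (enclosed pixel count) and perimeter (chain length of the traced
  boundary: 1 per axial step, sqrt(2) per diagonal step);
- major axis (rotating-calipers diameter of the convex hull) and minor axis
  (maximal shape extent perpendicular to the major-axis direction);
- elongation = major/minor;
- rectangularity = area / minimum-area enclosing rotated rectangle;
- eccentricity = sqrt(1 - minor^2/major^2);
- compactness = 4*pi*area / perimeter^2 (1 for an ideal circle); its
  reciprocal is also reported as ``roughness``.

A mechanically damaged kernel loses part of its body: its area and
compactness drop while elongation and eccentricity rise, which is the
signature the classifier learns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hull import convex_hull, trace_boundary

__all__ = [
    "KernelRecord",
    "FEATURE_NAMES",
    "area",
    "perimeter",
    "principal_axes",
    "elongation",
    "rectangularity",
    "min_area_rect_area",
    "eccentricity",
    "compactness",
    "features_from_mask",
    "extract_all",
]

FEATURE_NAMES = (
    "area",
    "perimeter",
    "major_axis",
    "minor_axis",
    "elongation",
    "rectangularity",
    "eccentricity",
    "compactness",
)


@dataclass
class KernelRecord:
    """One separated kernel: 8 shape descriptors plus its damage label."""

    id: int
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    elongation: float
    rectangularity: float
    eccentricity: float
    compactness: float
    roughness: float = field(default=float("nan"))
    label: str = "unknown"

    def vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=np.float64)


def _fill_contour(contour: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Rasterize a closed boundary and fill its interior; returns (patch, offset)."""
    contour = np.asarray(contour)
    r0, c0 = contour[:, 0].min(), contour[:, 1].min()
    patch = np.zeros(
        (contour[:, 0].max() - r0 + 1, contour[:, 1].max() - c0 + 1), dtype=bool
    )
    patch[contour[:, 0] - r0, contour[:, 1] - c0] = True
    return ndimage.binary_fill_holes(patch), (int(r0), int(c0))


def area(shape: np.ndarray) -> float:
    """Pixels enclosed by (and on) a contour, or foreground count of a mask."""
    shape = np.asarray(shape)
    if shape.dtype == bool:
        return float(shape.sum())
    patch, _ = _fill_contour(shape)
    return float(patch.sum())


def perimeter(contour: np.ndarray) -> float:
    """Chain length of a closed boundary: axial steps count 1, diagonal sqrt(2)."""
    contour = np.asarray(contour, dtype=np.float64)
    if contour.shape[0] < 2:
        return 0.0
    steps = np.abs(np.diff(np.vstack([contour, contour[:1]]), axis=0))
    diagonal = (steps.max(axis=1) > 0) & (steps.min(axis=1) > 0)
    axial = (steps.sum(axis=1) > 0) & ~diagonal
    return float(axial.sum() + math.sqrt(2.0) * diagonal.sum())


def principal_axes(contour: np.ndarray) -> tuple[float, float]:
    """Major axis (hull diameter) and maximal extent perpendicular to it.

    The major axis is the largest pairwise distance between convex-hull
    vertices; the minor axis is the point-span of the shape measured
    perpendicular to the major-axis direction. Raises for degenerate
    (collinear) contours.
    """
    hull = convex_hull(np.asarray(contour))
    diff = hull[:, None, :] - hull[None, :, :]
    d2 = (diff**2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    major = math.sqrt(d2[i, j])
    if major == 0:
        raise ValueError("degenerate contour: zero diameter")
    axis_dir = (hull[j] - hull[i]) / major
    normal = np.array([-axis_dir[1], axis_dir[0]])
    proj = np.asarray(contour, dtype=np.float64) @ normal
    minor = float(proj.max() - proj.min())
    if minor == 0:
        raise ValueError("degenerate contour: zero width")
    return float(major), minor


def elongation(major: float, minor: float) -> float:
    """Major-to-minor axis ratio (>= 1 for proper axes)."""
    return major / minor


def min_area_rect_area(contour: np.ndarray) -> float:
    """Area of the minimum-area enclosing rotated rectangle (rotating calipers).

    One side of the optimal rectangle is collinear with a hull edge; spans are
    widened by one pixel per dimension so a filled W x H rectangle scores
    exactly W*H.
    """
    hull = convex_hull(np.asarray(contour)).astype(np.float64)
    edges = np.roll(hull, -1, axis=0) - hull
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    best = math.inf
    for e, ln in zip(edges, lengths):
        if ln == 0:
            continue
        u = e / ln
        v = np.array([-u[1], u[0]])
        pu = hull @ u
        pv = hull @ v
        a = (pu.max() - pu.min() + 1.0) * (pv.max() - pv.min() + 1.0)
        best = min(best, a)
    if not math.isfinite(best):
        raise ValueError("degenerate hull")
    return best


def rectangularity(area_px: float, contour: np.ndarray) -> float:
    """Area over minimum-area enclosing rotated rectangle, clipped to (0, 1]."""
    return min(1.0, area_px / min_area_rect_area(contour))


def eccentricity(major: float, minor: float) -> float:
    """sqrt(1 - minor^2/major^2); 0 for a circle, toward 1 for a sliver."""
    if major <= 0:
        raise ValueError("major axis must be positive")
    ratio = min(1.0, (minor / major) ** 2)
    return math.sqrt(1.0 - ratio)


def compactness(area_px: float, perimeter_px: float) -> float:
    """Isoperimetric ratio 4*pi*area/perimeter^2."""
    if perimeter_px <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * math.pi * area_px / perimeter_px**2


def features_from_mask(mask: np.ndarray, record_id: int = 0, label: str = "unknown") -> KernelRecord:
    """All 8 descriptors of a single-region boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    contour = trace_boundary(mask)
    a = float(mask.sum())
    p = perimeter(contour)
    major, minor = principal_axes(contour)
    if minor > major:
        major, minor = minor, major
    comp = compactness(a, p)
    return KernelRecord(
        id=record_id,
        area=a,
        perimeter=p,
        major_axis=major,
        minor_axis=minor,
        elongation=elongation(major, minor),
        rectangularity=rectangularity(a, contour),
        eccentricity=eccentricity(major, minor),
        compactness=comp,
        roughness=1.0 / comp,
    )


def extract_all(mask: np.ndarray, contours: list[np.ndarray]) -> list[KernelRecord]:
    """One record per contour. ``mask`` restricts each filled contour region."""
    mask = np.asarray(mask, dtype=bool)
    records = []
    for i, contour in enumerate(contours):
        patch, (r0, c0) = _fill_contour(contour)
        sl = (slice(r0, r0 + patch.shape[0]), slice(c0, c0 + patch.shape[1]))
        patch &= mask[sl]
        rec = features_from_mask(patch, record_id=i)
        records.append(rec)
    return records
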