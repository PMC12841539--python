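"""Marker-based watershed for coarse separation of touching kernels.

The stage treats the binary foreground as terrain: the Euclidean distance
transform is high at kernel cores and dips at adhesion necks, so flooding the
negated distance field from per-core markers places watershed lines across
necks. A Sobel gradient magnitude (Gaussian-smoothed, sigma 1.5 by default)
is computed as the alternative flooding height for gradient-driven mode.

Markers are the 8-connected components of the region where the distance
transform reaches at least ``peak_fraction`` of its connected-component
maximum; this never fragments a single convex kernel (the thresholded core of
a convex blob is connected), at the price of leaving heavily overlapped pairs
for the convexity-defect refinement stage to split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed as _skimage_watershed

__all__ = [
    "GradientField",
    "BOUNDARY_LABEL",
    "sobel_gradient",
    "smooth_gradient",
    "distance_transform",
    "extract_markers",
    "watershed_flood",
    "merge_boundary_pixels",
    "segment_mask",
]

#: Reserved label carried by watershed-line pixels in a label map.
BOUNDARY_LABEL = -1

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = SOBEL_X.T


@dataclass(frozen=True)
class GradientField:
    """Signed Sobel responses plus magnitude rescaled to [0, 255]."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray


def sobel_gradient(img: np.ndarray) -> GradientField:
    """3x3 Sobel gradient of a grayscale image.

    Borders are replicate-padded. The magnitude ``sqrt(gx^2 + gy^2)`` is
    linearly rescaled to [0, 255] (left at zero for a constant image).
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("sobel_gradient expects a single-channel image")
    gx = ndimage.correlate(img, SOBEL_X, mode="nearest")
    gy = ndimage.correlate(img, SOBEL_Y, mode="nearest")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag * (255.0 / peak)
    return GradientField(gx=gx, gy=gy, magnitude=mag)


def smooth_gradient(field: GradientField, sigma: float = 1.5) -> GradientField:
    """Gaussian-smooth the gradient magnitude (truncated at radius 3*sigma).

    The smoothed magnitude is rescaled back to [0, 255]; the signed responses
    are carried through untouched.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    mag = ndimage.gaussian_filter(field.magnitude, sigma=sigma, truncate=3.0)
    # smoothing only averages, so the field stays within [0, max]; rescale
    # only if numerical overshoot leaves the 8-bit range
    peak = mag.max()
    if peak > 255.0:
        mag = mag * (255.0 / peak)
    return GradientField(gx=field.gx, gy=field.gy, magnitude=mag)


def distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact Euclidean distance of every pixel to the nearest background pixel."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        raise ValueError("mask has no background pixel; distances are undefined")
    return ndimage.distance_transform_edt(mask)


def extract_markers(
    distance: np.ndarray,
    mask: np.ndarray,
    peak_fraction: float = 0.4,
    min_marker_area: int = 9,
) -> np.ndarray:
    """Label kernel-core markers from the distance field.

    Within each 8-connected foreground component, pixels reaching at least
    ``peak_fraction`` of the component's distance maximum form the core
    region; its 8-connected components, minus any smaller than
    ``min_marker_area``, are labelled 1..K.

    Raises
    ------
    ValueError
        If no marker survives — lower ``peak_fraction`` (or
        ``min_marker_area``) for very small or thin objects.
    """
    if not 0 < peak_fraction < 1:
        raise ValueError("peak_fraction must lie in (0, 1)")
    mask = np.asarray(mask, dtype=bool)
    eight = np.ones((3, 3), dtype=bool)
    comps, n_comp = ndimage.label(mask, structure=eight)
    core = np.zeros_like(mask)
    if n_comp:
        comp_max = ndimage.maximum(distance, labels=comps, index=np.arange(1, n_comp + 1))
        comp_max = np.atleast_1d(comp_max)
        thresh_map = np.zeros_like(distance)
        thresh_map[mask] = peak_fraction * comp_max[comps[mask] - 1]
        core = mask & (distance >= thresh_map)
    markers, n_mark = ndimage.label(core, structure=eight)
    if n_mark and min_marker_area > 1:
        areas = np.bincount(markers.ravel())
        keep = np.flatnonzero(areas >= min_marker_area)
        keep = keep[keep > 0]
        relabel = np.zeros(n_mark + 1, dtype=np.int32)
        relabel[keep] = np.arange(1, keep.size + 1)
        markers = relabel[markers]
        n_mark = keep.size
    if n_mark == 0:
        raise ValueError(
            "no markers found; lower peak_fraction or min_marker_area for this mask"
        )
    return markers.astype(np.int32)


def watershed_flood(
    height: np.ndarray,
    markers: np.ndarray,
    mask: np.ndarray,
    keep_lines: bool = True,
) -> np.ndarray:
    """Priority-flood the height surface from markers, restricted to the mask.

    Returns a label map: 0 outside the mask, marker labels inside, and — when
    ``keep_lines`` — ``BOUNDARY_LABEL`` on single-pixel watershed lines
    between basins. The flood frontier is 4-connected and deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    markers = np.asarray(markers)
    if markers.max() < 1:
        raise ValueError("at least one marker is required")
    if ((markers > 0) & ~mask).any():
        raise ValueError("markers must lie inside the mask")
    labels = _skimage_watershed(
        np.asarray(height, dtype=np.float64),
        markers=markers.astype(np.int32),
        mask=mask,
        connectivity=1,
        watershed_line=True,
    ).astype(np.int32)
    out = labels
    if keep_lines:
        out = np.where(mask & (labels == 0), np.int32(BOUNDARY_LABEL), labels)
    else:
        out = merge_boundary_pixels(
            np.where(mask & (labels == 0), np.int32(BOUNDARY_LABEL), labels)
        )
    return out


def merge_boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Assign watershed-line pixels to the adjacent basin with the lowest label.

    Needed before contour extraction: every foreground pixel must belong to a
    basin so region boundaries are closed.
    """
    labels = np.asarray(labels).copy()
    line = labels == BOUNDARY_LABEL
    if not line.any():
        return labels
    big = np.iinfo(np.int32).max
    # iterate: a line pixel takes the smallest positive neighbor label
    for _ in range(labels.size):
        line = labels == BOUNDARY_LABEL
        if not line.any():
            break
        padded = np.full((labels.shape[0] + 2, labels.shape[1] + 2), 0, dtype=np.int64)
        padded[1:-1, 1:-1] = labels
        best = np.full(labels.shape, big, dtype=np.int64)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                neigh = padded[1 + dr : padded.shape[0] - 1 + dr,
                               1 + dc : padded.shape[1] - 1 + dc]
                cand = np.where(neigh > 0, neigh, big)
                best = np.minimum(best, cand)
        fill = line & (best < big)
        if not fill.any():
            # isolated line pixels with no labelled neighbor: drop to background
            labels[line] = 0
            break
        labels[fill] = best[fill].astype(labels.dtype)
    return labels


def segment_mask(
    mask: np.ndarray,
    peak_fraction: float = 0.4,
    min_marker_area: int = 9,
    height: np.ndarray | None = None,
) -> np.ndarray:
    """Convenience: distance transform, markers, flood, merge lines.

    ``height`` defaults to the negated distance transform; pass a smoothed
    gradient magnitude for gradient-driven flooding.
    """
    d = distance_transform(mask)
    markers = extract_markers(d, mask, peak_fraction, min_marker_area)
    h = -d if height is None else height
    labels = watershed_flood(h, markers, mask, keep_lines=True)
    labels = merge_boundary_pixels(labels)
    # components too small to earn a marker are still objects (debris or
    # noise contours); label them so downstream area filtering decides
    orphan = mask & (labels == 0)
    if orphan.any():
        extra, n_extra = ndimage.label(orphan, structure=np.ones((3, 3), bool))
        base = int(labels.max())
        labels = np.where(extra > 0, extra + base, labels)
    return labels
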