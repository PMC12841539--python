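"""Image preprocessing: grayscale conversion, Otsu binarization, binary morphology.

The preprocessing chain turns an RGB scene of bright kernels on a dark matte
background into a clean binary foreground mask:

1. luminance grayscale, ``Gray = 0.299 R + 0.587 G + 0.114 B``;
2. automatic thresholding by maximizing the between-class (inter-class)
   variance of the gray histogram (Otsu's method);
3. binary opening (removes bright speckle noise) followed by closing
   (fills pinholes inside kernels).

The morphology operators are literal set-space definitions — erosion as the
set of translations under which the structuring element fits inside the
foreground, dilation as the Minkowski sum — with everything outside the image
treated as background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateHistogramError",
    "HistogramStats",
    "to_grayscale",
    "otsu_threshold",
    "binarize",
    "structuring_element",
    "erode",
    "dilate",
    "opening",
    "closing",
    "clean_mask",
]

#: Luminance weights for R, G, B (ITU-R BT.601).
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class DegenerateHistogramError(ValueError):
    """Raised when an image has a single gray level and cannot be thresholded."""


@dataclass(frozen=True)
class HistogramStats:
    """Per-threshold statistics of the Otsu criterion on a 256-level histogram.

    Attributes
    ----------
    p : (256,) array
        Gray-level probabilities, summing to 1.
    omega1, omega2 : (256,) arrays
        Cumulative class probabilities of the dark-to-``t`` class and the
        ``t+1``-to-255 class.
    mu1, mu2 : (256,) arrays
        Class mean gray levels (NaN where a class is empty).
    mu : float
        Global mean gray level.
    sigma_b2 : (256,) array
        Between-class variance at every candidate threshold.
    t_optimal : int
        Smallest threshold maximizing ``sigma_b2``.
    """

    p: np.ndarray
    omega1: np.ndarray
    omega2: np.ndarray
    mu1: np.ndarray
    mu2: np.ndarray
    mu: float
    sigma_b2: np.ndarray
    t_optimal: int


def _require_uint8(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if np.issubdtype(img.dtype, np.integer) and img.min() >= 0 and img.max() <= 255:
            img = img.astype(np.uint8)
        else:
            raise ValueError("expected an 8-bit image with values in [0, 255]")
    return img


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert a 3-channel 8-bit image to single-channel luminance.

    Per pixel ``Gray = 0.299 R + 0.587 G + 0.114 B``, rounded half-up to the
    nearest integer and clipped to [0, 255]. A single-channel input is passed
    through unchanged with a warning (the conversion is idempotent).
    """
    img = _require_uint8(img)
    if img.ndim == 2:
        warnings.warn("to_grayscale called on a single-channel image; passing through")
        return img
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    w = np.asarray(GRAY_WEIGHTS)
    gray = img.astype(np.float64) @ w
    # round half-up, not banker's rounding: floor(x + 0.5)
    gray = np.floor(gray + 0.5)
    return np.clip(gray, 0, 255).astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> tuple[int, HistogramStats]:
    """Otsu threshold of a grayscale image by maximum between-class variance.

    A candidate threshold ``t`` splits levels into a dark class [0, t] and a
    bright class [t+1, 255]; the returned ``t`` maximizes the between-class
    variance, ties broken by the smallest ``t``.

    Raises
    ------
    DegenerateHistogramError
        If the image holds a single gray level (both classes can never be
        non-empty, the criterion is identically zero).
    """
    img = _require_uint8(img)
    if img.ndim == 3:
        raise ValueError("otsu_threshold expects a single-channel image")
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("image has fewer than two distinct gray levels")
    p = hist / n
    levels = np.arange(256, dtype=np.float64)
    omega1 = np.cumsum(p)
    omega2 = 1.0 - omega1
    cummean = np.cumsum(levels * p)
    mu = cummean[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = cummean / omega1
        mu2 = (mu - cummean) / omega2
        sigma_b2 = omega1 * (mu1 - mu) ** 2 + omega2 * (mu2 - mu) ** 2
    # an empty class carries zero probability weight, hence zero variance term
    sigma_b2 = np.where(np.isfinite(sigma_b2), sigma_b2, 0.0)
    sigma_b2[(omega1 <= 0) | (omega2 <= 0)] = 0.0
    # smallest t on the maximizing plateau; the 1e-9 relative band absorbs
    # floating-point noise across empty histogram levels
    peak = float(sigma_b2.max())
    t_opt = int(np.flatnonzero(sigma_b2 >= peak - 1e-9 * max(peak, 1.0)).min())
    stats = HistogramStats(
        p=p, omega1=omega1, omega2=omega2, mu1=mu1, mu2=mu2, mu=float(mu),
        sigma_b2=sigma_b2, t_optimal=t_opt,
    )
    return t_opt, stats


def binarize(img: np.ndarray, t: int, bright_foreground: bool = True) -> np.ndarray:
    """Threshold a grayscale image into a boolean mask.

    With ``bright_foreground`` (the default; kernels are brighter than the
    matte background) pixels strictly above ``t`` become foreground;
    otherwise pixels at or below ``t`` do.
    """
    if not 0 <= t <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    img = _require_uint8(img)
    return img > t if bright_foreground else img <= t


# ---------------------------------------------------------------------------
# binary morphology


def structuring_element(shape: str = "ellipse", size: int = 3) -> np.ndarray:
    """Small boolean structuring element: 'ellipse' (disk), 'cross' or 'square'."""
    if size < 1 or size % 2 == 0:
        raise ValueError("size must be a positive odd integer")
    r = size // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    if shape == "ellipse":
        return (yy**2 + xx**2) <= r**2 + (1 if size > 3 else 0)
    if shape == "cross":
        return (yy == 0) | (xx == 0)
    if shape == "square":
        return np.ones((size, size), dtype=bool)
    raise ValueError(f"unknown structuring element shape {shape!r}")


def _offsets(se: np.ndarray, anchor: tuple[int, int] | None) -> np.ndarray:
    se = np.asarray(se, dtype=bool)
    if not se.any():
        raise ValueError("structuring element has no set elements")
    if anchor is None:
        anchor = (se.shape[0] // 2, se.shape[1] // 2)
    ar, ac = anchor
    if not (0 <= ar < se.shape[0] and 0 <= ac < se.shape[1]):
        raise ValueError("anchor must lie inside the structuring element")
    rr, cc = np.nonzero(se)
    return np.stack([rr - ar, cc - ac], axis=1)


def _shift(mask: np.ndarray, dr: int, dc: int, fill: bool) -> np.ndarray:
    """Translate a boolean mask by (dr, dc), padding with `fill`."""
    out = np.full_like(mask, fill)
    h, w = mask.shape
    rs_src = slice(max(0, -dr), min(h, h - dr))
    cs_src = slice(max(0, -dc), min(w, w - dc))
    rs_dst = slice(max(0, dr), min(h, h + dr))
    cs_dst = slice(max(0, dc), min(w, w + dc))
    if rs_src.start < rs_src.stop and cs_src.start < cs_src.stop:
        out[rs_dst, cs_dst] = mask[rs_src, cs_src]
    return out


def erode(mask: np.ndarray, se: np.ndarray, anchor: tuple[int, int] | None = None) -> np.ndarray:
    """Binary erosion: translations under which the element fits in the foreground.

    Pixels outside the image count as background, so foreground touching the
    border erodes away wherever the element overhangs the edge.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.ones_like(mask)
    for dr, dc in _offsets(se, anchor):
        out &= _shift(mask, -dr, -dc, fill=False)
    return out


def dilate(mask: np.ndarray, se: np.ndarray, anchor: tuple[int, int] | None = None) -> np.ndarray:
    """Binary dilation: Minkowski sum of the foreground with the element."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    for dr, dc in _offsets(se, anchor):
        out |= _shift(mask, dr, dc, fill=False)
    return out


def opening(mask: np.ndarray, se: np.ndarray, anchor: tuple[int, int] | None = None) -> np.ndarray:
    """Erosion followed by dilation; removes speckles smaller than the element."""
    return dilate(erode(mask, se, anchor), se, anchor)


def closing(mask: np.ndarray, se: np.ndarray, anchor: tuple[int, int] | None = None) -> np.ndarray:
    """Dilation followed by erosion; fills holes smaller than the element."""
    return erode(dilate(mask, se, anchor), se, anchor)


def clean_mask(mask: np.ndarray, se: np.ndarray | None = None) -> np.ndarray:
    """Default denoising used by the pipeline: one opening, then one closing."""
    if se is None:
        se = structuring_element("ellipse", 3)
    return closing(opening(mask, se), se)
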