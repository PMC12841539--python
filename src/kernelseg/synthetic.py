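"""Seeded generator of adhered-kernel scenes with exact per-kernel ground truth.

Emulates laboratory acquisition of corn kernels scattered on a dark matte
background: 80-150 bright elliptical kernels per 2000 x 1500 frame, random
placement that produces natural adhesion clusters, a fraction of kernels
carrying a mechanical-damage bite, mild linear illumination non-uniformity
and sparse salt-and-pepper speckles.

Kernels are filled ellipses with random orientation (the convexity
assumption the watershed / convex-hull method exploits). An adhered kernel
is placed so its ellipse overlaps a previously placed anchor by at least one
pixel, with the pairwise overlap capped at ``overlap_cap`` of the smaller
kernel's area. A damaged kernel is its ellipse minus a circular bite whose
center and radius are solved numerically so that the bite penetrates deep
into the body (large area loss, higher elongation, the damage signature)
while the realized convexity-defect depth of the notch matches a target
drawn from ``bite_depth_range``. With the default range the notch stays
below the 8 px adhesion-defect threshold: a genuinely broken kernel has a
near-chord cut edge, unlike the deep pinch of an adhesion neck.

All randomness flows from one integer-seeded generator; identical specs give
byte-identical scenes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import FEATURE_NAMES, features_from_mask
from .hull import find_defects, trace_boundary

__all__ = [
    "SceneSpec",
    "InstanceMask",
    "SceneGroundTruth",
    "SceneCapacityError",
    "generate_scene",
    "generate_feature_dataset",
    "write_scene",
]

_EIGHT = np.ones((3, 3), dtype=bool)

#: CSV schema of exported feature tables.
FEATURE_COLUMNS = ["id", *FEATURE_NAMES, "label"]


class SceneCapacityError(RuntimeError):
    """Raised when kernels cannot be placed (image too small for n_kernels)."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene; defaults mirror the lab acquisition."""

    image_width: int = 2000
    image_height: int = 1500
    n_kernels: int = 120
    adhesion_probability: float = 0.5
    damage_fraction: float = 0.3
    kernel_axis_range: tuple[float, float] = (40.0, 60.0)
    bite_depth_range: tuple[float, float] = (3.0, 6.0)
    overlap_cap: float = 0.45
    background_level: int = 30
    kernel_level_range: tuple[int, int] = (140, 200)
    illumination_slope: float = 0.005
    speckle_density: float = 5e-4
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_kernels < 1:
            raise ValueError("n_kernels must be >= 1")
        if self.kernel_axis_range[0] < 4:
            raise ValueError("minimum semi-axis must be >= 4 px")
        if self.kernel_axis_range[0] > self.kernel_axis_range[1]:
            raise ValueError("kernel_axis_range must be (min, max)")
        for name in ("adhesion_probability", "damage_fraction", "overlap_cap",
                     "speckle_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.kernel_level_range[0] <= self.background_level + 30:
            raise ValueError(
                "kernel gray levels must exceed background_level + 30 "
                "(guarantees a bimodal histogram)"
            )
        if self.bite_depth_range[0] <= 0 or self.bite_depth_range[0] > self.bite_depth_range[1]:
            raise ValueError("bite_depth_range must be positive and ordered")


@dataclass
class InstanceMask:
    """One kernel's binary mask stored as a bounding-box patch."""

    row0: int
    col0: int
    patch: np.ndarray  # bool, local

    @property
    def bbox_slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.patch.shape[0]),
            slice(self.col0, self.col0 + self.patch.shape[1]),
        )

    @property
    def area(self) -> int:
        return int(self.patch.sum())

    def dense(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        out[self.bbox_slices] = self.patch
        return out

    def overlap_pixels(self, other: "InstanceMask") -> int:
        r0 = max(self.row0, other.row0)
        c0 = max(self.col0, other.col0)
        r1 = min(self.row0 + self.patch.shape[0], other.row0 + other.patch.shape[0])
        c1 = min(self.col0 + self.patch.shape[1], other.col0 + other.patch.shape[1])
        if r0 >= r1 or c0 >= c1:
            return 0
        a = self.patch[r0 - self.row0 : r1 - self.row0, c0 - self.col0 : c1 - self.col0]
        b = other.patch[r0 - other.row0 : r1 - other.row0, c0 - other.col0 : c1 - other.col0]
        return int(np.logical_and(a, b).sum())


@dataclass
class SceneGroundTruth:
    """Exact per-kernel truth for one generated scene."""

    instance_masks: list[InstanceMask]
    damage_labels: list[str]
    adhesion_cluster_ids: list[int]
    true_count: int
    foreground: np.ndarray = field(repr=False)  # union of masks, bool
    clean_image: np.ndarray = field(repr=False)  # grayscale, pre-noise


def _ellipse_patch(a: float, b: float, phi: float) -> np.ndarray:
    """Boolean patch of an ellipse with semi-axes (a, b) rotated by phi."""
    r = int(math.ceil(max(a, b))) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1].astype(np.float64)
    c, s = math.cos(phi), math.sin(phi)
    u = xx * c + yy * s
    v = -xx * s + yy * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _notch_depth(patch: np.ndarray) -> float:
    """Deepest convexity defect of a single-region patch, 0 if none."""
    contour = trace_boundary(patch)
    defs = find_defects(contour, depth_threshold=0.5)
    return defs[0].depth if defs else 0.0


def _apply_bite(
    patch: np.ndarray, a: float, b: float, phi: float,
    target_depth: float, rng: np.random.Generator,
) -> np.ndarray | None:
    """Carve a circular bite into an ellipse patch.

    Penetration is drawn as 0.25-0.6 of the minor semi-axis; the bite-circle
    radius is then bisected so the realized convexity-defect depth of the
    notch lands within ~0.5 px of ``target_depth`` (large radii make the cut
    edge flatter, hence shallower defects). Returns None if no valid bite was
    found (caller redraws).
    """
    r0 = patch.shape[0] // 2
    theta = rng.uniform(0.0, 2.0 * math.pi)
    # boundary point and outward normal of the rotated ellipse
    c, s = math.cos(phi), math.sin(phi)
    ex, ey = a * math.cos(theta), b * math.sin(theta)
    px = ex * c - ey * s
    py = ex * s + ey * c
    nx0 = math.cos(theta) / a
    ny0 = math.sin(theta) / b
    nx = nx0 * c - ny0 * s
    ny = nx0 * s + ny0 * c
    nn = math.hypot(nx, ny)
    nx, ny = nx / nn, ny / nn
    # penetration deep enough to reproduce observed damage severity: broken
    # kernels lose roughly a third to a half of their body
    depth_pen = max(rng.uniform(0.5, 0.9) * b, target_depth + 2.0)

    yy, xx = np.mgrid[-r0 : r0 + 1, -r0 : r0 + 1].astype(np.float64)

    def carve(radius: float) -> np.ndarray | None:
        ox = px + (radius - depth_pen) * nx
        oy = py + (radius - depth_pen) * ny
        bite = (xx - ox) ** 2 + (yy - oy) ** 2 <= radius**2
        out = patch & ~bite
        if out.sum() < 0.3 * patch.sum():
            return None
        lab, n = ndimage.label(out, structure=_EIGHT)
        if n != 1:
            return None
        return out

    lo, hi = depth_pen, 60.0 * depth_pen
    out_hi = carve(hi)
    if out_hi is not None and _notch_depth(out_hi) >= target_depth:
        return _roughen_cut(out_hi, patch, target_depth, rng)
    best = None
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        cand = carve(mid)
        if cand is None:
            hi = mid  # radius too large removed too much; shrink
            continue
        d = _notch_depth(cand)
        if abs(d - target_depth) <= 0.5:
            return _roughen_cut(cand, patch, target_depth, rng)
        if d > target_depth:
            lo = mid  # notch too deep -> flatten with a larger radius
            best = cand
        else:
            hi = mid
    if best is None:
        return None
    return _roughen_cut(best, patch, target_depth, rng)


def _roughen_cut(
    out: np.ndarray, original: np.ndarray, target_depth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Roughen the fracture edge of a bitten kernel with small dents.

    A mechanical break leaves an irregular edge, not a clean arc: the extra
    boundary length is the roughness signature that separates damaged from
    merely truncated kernels. Dents are 1-2.5 px discs subtracted along the
    cut edge only; any dent that disconnects the kernel or drives the overall
    notch depth toward the adhesion-defect threshold is rejected.
    """
    edge = out & ~ndimage.binary_erosion(out, _EIGHT)
    interior = ndimage.binary_erosion(original, _EIGHT, iterations=2)
    cut_edge = edge & interior
    coords = np.argwhere(cut_edge)
    if coords.shape[0] < 4:
        return out
    n_dents = int(rng.integers(4, 9))
    yy, xx = np.mgrid[: out.shape[0], : out.shape[1]].astype(np.float64)
    depth_ceiling = min(target_depth + 1.0, 7.0)
    for _ in range(n_dents):
        p = coords[rng.integers(coords.shape[0])]
        r = rng.uniform(1.0, 2.5)
        cand = out & ~(((yy - p[0]) ** 2 + (xx - p[1]) ** 2) <= r**2)
        lab, n = ndimage.label(cand, structure=_EIGHT)
        if n != 1:
            continue
        if _notch_depth(cand) > depth_ceiling:
            continue
        out = cand
    return out


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render one scene; deterministic for a fixed ``spec.rng_seed``.

    Returns the 3-channel 8-bit image (illumination ramp and speckles
    applied) and the ground truth (pre-noise instance masks, damage labels,
    adhesion cluster ids).

    Raises
    ------
    SceneCapacityError
        If rejection sampling cannot place all kernels (image too small).
    """
    h, w = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.rng_seed)
    masks: list[InstanceMask] = []
    majors: list[float] = []
    occluded: list[int] = []  # cumulative overlap pixels per placed kernel
    damage_flags = rng.random(spec.n_kernels) < spec.damage_fraction
    max_attempts = 300

    for k in range(spec.n_kernels):
        placed = None
        for _ in range(max_attempts):
            ax1, ax2 = rng.uniform(*spec.kernel_axis_range, size=2)
            a, b = max(ax1, ax2), min(ax1, ax2)
            phi = rng.uniform(0.0, math.pi)
            patch = _ellipse_patch(a, b, phi)
            r = patch.shape[0] // 2
            adhere = bool(masks) and rng.random() < spec.adhesion_probability
            if adhere:
                j = int(rng.integers(len(masks)))
                anchor = masks[j]
                acr = anchor.row0 + anchor.patch.shape[0] // 2
                acc = anchor.col0 + anchor.patch.shape[1] // 2
                psi = rng.uniform(0.0, 2.0 * math.pi)
                dist = rng.uniform(0.55, 0.98) * (a + majors[j])
                cr = int(round(acr + dist * math.sin(psi)))
                cc = int(round(acc + dist * math.cos(psi)))
            else:
                cr = int(rng.integers(r, h - r)) if h > 2 * r else -1
                cc = int(rng.integers(r, w - r)) if w > 2 * r else -1
            if cr < r or cc < r or cr >= h - r or cc >= w - r:
                continue
            cand = InstanceMask(row0=cr - r, col0=cc - r, patch=patch)
            area = cand.area
            ok = True
            anchor_overlap = 0
            overlaps = []
            for j2, m in enumerate(masks):
                ov = cand.overlap_pixels(m)
                overlaps.append(ov)
                # pairwise cap, plus cumulative occlusion caps so no kernel
                # ends up mostly buried under several neighbors
                if ov > spec.overlap_cap * min(area, m.area):
                    ok = False
                    break
                if ov and occluded[j2] + ov > spec.overlap_cap * m.area:
                    ok = False
                    break
                if adhere and j2 == j:
                    anchor_overlap = ov
                if not adhere and ov > 0:
                    ok = False
                    break
            if ok and sum(overlaps) > spec.overlap_cap * area:
                ok = False
            if not ok:
                continue
            if adhere and anchor_overlap < 1:
                continue
            if damage_flags[k]:
                target = rng.uniform(*spec.bite_depth_range)
                bitten = _apply_bite(patch, a, b, phi, target, rng)
                if bitten is None:
                    continue
                cand = InstanceMask(row0=cr - r, col0=cc - r, patch=bitten)
            placed = cand
            break
        if placed is None:
            raise SceneCapacityError(
                f"could not place kernel {k + 1}/{spec.n_kernels} after "
                f"{max_attempts} attempts; enlarge the image or reduce n_kernels"
            )
        for j2, ov in enumerate(overlaps):
            occluded[j2] += ov
        occluded.append(sum(overlaps))
        masks.append(placed)
        majors.append(a)

    # adhesion clusters: union-find over touching/overlapping realized masks
    parent = list(range(len(masks)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if _touching(masks[i], masks[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    cluster_ids = [find(i) for i in range(len(masks))]

    # compose the clean grayscale scene
    clean = np.full((h, w), spec.background_level, dtype=np.uint8)
    levels = rng.integers(
        spec.kernel_level_range[0], spec.kernel_level_range[1] + 1, size=len(masks)
    )
    foreground = np.zeros((h, w), dtype=bool)
    for m, lev in zip(masks, levels):
        sl = m.bbox_slices
        clean[sl][m.patch] = lev
        foreground[sl] |= m.patch

    img = clean.astype(np.float64)
    if spec.illumination_slope:
        ramp = spec.illumination_slope * (np.arange(w, dtype=np.float64) - w / 2.0)
        img = img + ramp[None, :]
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    n_speck = int(round(spec.speckle_density * h * w))
    if n_speck:
        rr = rng.integers(0, h, size=n_speck)
        cc = rng.integers(0, w, size=n_speck)
        salt = rng.random(n_speck) < 0.5
        img[rr[salt], cc[salt]] = 255
        img[rr[~salt], cc[~salt]] = 0
    rgb = np.repeat(img[:, :, None], 3, axis=2)

    gt = SceneGroundTruth(
        instance_masks=masks,
        damage_labels=["damaged" if f else "intact" for f in damage_flags],
        adhesion_cluster_ids=cluster_ids,
        true_count=len(masks),
        foreground=foreground,
        clean_image=clean,
    )
    return rgb, gt


def _touching(a: InstanceMask, b: InstanceMask) -> bool:
    """True when two patch masks overlap or are 8-adjacent."""
    r0 = max(a.row0, b.row0) - 1
    c0 = max(a.col0, b.col0) - 1
    r1 = min(a.row0 + a.patch.shape[0], b.row0 + b.patch.shape[0]) + 1
    c1 = min(a.col0 + a.patch.shape[1], b.col0 + b.patch.shape[1]) + 1
    if r0 >= r1 or c0 >= c1:
        return False
    ha, wa = r1 - r0, c1 - c0
    pa = np.zeros((ha, wa), dtype=bool)
    pb = np.zeros((ha, wa), dtype=bool)
    _paste(pa, a, r0, c0)
    _paste(pb, b, r0, c0)
    return bool((ndimage.binary_dilation(pa, _EIGHT) & pb).any())


def _paste(canvas: np.ndarray, m: InstanceMask, r0: int, c0: int) -> None:
    rr = m.row0 - r0
    cc = m.col0 - c0
    h, w = canvas.shape
    rs = slice(max(0, rr), min(h, rr + m.patch.shape[0]))
    cs = slice(max(0, cc), min(w, cc + m.patch.shape[1]))
    prs = slice(rs.start - rr, rs.stop - rr)
    pcs = slice(cs.start - cc, cs.stop - cc)
    canvas[rs, cs] |= m.patch[prs, pcs]


def ground_truth_label_map(gt: SceneGroundTruth) -> np.ndarray:
    """16-bit label map of the ground truth; overlap pixels take the later kernel."""
    out = np.zeros(gt.foreground.shape, dtype=np.uint16)
    for i, m in enumerate(gt.instance_masks, start=1):
        out[m.bbox_slices][m.patch] = i
    return out


def scene_feature_table(gt: SceneGroundTruth, image_id: int = 0) -> pd.DataFrame:
    """Per-kernel 8-feature table computed on the ground-truth masks."""
    rows = []
    for i, (m, lab) in enumerate(zip(gt.instance_masks, gt.damage_labels)):
        rec = features_from_mask(m.patch, record_id=i, label=lab)
        row = {"id": i, **{n: getattr(rec, n) for n in FEATURE_NAMES}, "label": lab}
        row["image_id"] = image_id
        rows.append(row)
    return pd.DataFrame(rows, columns=[*FEATURE_COLUMNS, "image_id"])


def generate_feature_dataset(
    spec_list: list[SceneSpec], split_fraction: float = 0.8, rng_seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Image-level train/test split of per-kernel feature tables.

    Every scene is assigned to exactly one split (no kernel-level leakage).
    ``split_fraction`` is the training share; both splits must be non-empty.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must lie in (0, 1)")
    n = len(spec_list)
    n_train = int(round(split_fraction * n))
    if n_train < 1 or n - n_train < 1:
        raise ValueError("both splits must contain at least one image")
    order = np.random.default_rng(rng_seed).permutation(n)
    train_ids = set(order[:n_train].tolist())
    tables_train, tables_test = [], []
    for i, spec in enumerate(spec_list):
        _, gt = generate_scene(spec)
        table = scene_feature_table(gt, image_id=i)
        (tables_train if i in train_ids else tables_test).append(table)
    return (
        pd.concat(tables_train, ignore_index=True),
        pd.concat(tables_test, ignore_index=True),
    )


def write_scene(
    out_dir: str | Path, image: np.ndarray, gt: SceneGroundTruth, stem: str = "scene"
) -> dict[str, Path]:
    """Write a scene to disk: PNG image, 16-bit label TIFF, JSON ground truth."""
    import imageio.v3 as iio
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / f"{stem}.png",
        "labels": out_dir / f"{stem}_labels.tif",
        "truth": out_dir / f"{stem}_truth.json",
    }
    iio.imwrite(paths["image"], image)
    tifffile.imwrite(paths["labels"], ground_truth_label_map(gt))
    payload = {
        "true_count": gt.true_count,
        "damage_labels": gt.damage_labels,
        "adhesion_cluster_ids": [int(c) for c in gt.adhesion_cluster_ids],
    }
    paths["truth"].write_text(json.dumps(payload, indent=2))
    return paths
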