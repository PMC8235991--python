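"""Hand-crafted lesion descriptors: intensity statistics, co-occurrence
texture measures and region-geometry shape measures.

The 16-entry feature vector has a fixed, documented order (see
:data:`FEATURE_NAMES`).  Texture measures are computed on a normalized
symmetric gray-level co-occurrence matrix restricted to the masked region
(32 levels, displacement (0, 1) by default).  Axis lengths are the full
major/minor axes of the region's second-central-moment ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .denoise import validate_image

__all__ = [
    "FEATURE_NAMES",
    "RegionGeometry",
    "intensity_stats",
    "glcm",
    "texture_features",
    "shape_features",
    "extract_all",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "variance",
    "std",
    "contrast",
    "area",
    "rectangularity",
    "elongation",
    "irregularity_index",
    "form_factor",
    "eccentricity",
    "entropy",
    "perimeter",
    "homogeneity",
    "energy",
    "correlation",
    "hu_phi1",
)


@dataclass(frozen=True)
class RegionGeometry:
    major_axis: float
    minor_axis: float
    perimeter: float
    area: int


def _check_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise ValueError("mask shape must match image shape")
    return mask


def intensity_stats(img: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """(mean, population variance, std) of intensities inside the mask."""
    img = validate_image(img)
    mask = _check_mask(img, mask)
    if not mask.any():
        raise ValueError("empty mask")
    vals = img[mask]
    mean = float(vals.mean())
    var = float(vals.var())
    return mean, var, float(np.sqrt(var))


def glcm(
    img: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    displacement: tuple[int, int] = (0, 1),
) -> np.ndarray:
    """Normalized symmetric co-occurrence matrix over masked pixel pairs.

    Intensities are binned uniformly into ``levels`` levels over [0, 1];
    only pairs with both endpoints inside the mask are counted, each pair
    contributing to (i, j) and (j, i).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    img = validate_image(img)
    mask = _check_mask(img, mask)
    if mask.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    q = np.minimum((img * levels).astype(np.int64), levels - 1)

    dy, dx = displacement
    m, n = img.shape
    src = np.zeros_like(mask)
    y0, y1 = max(0, -dy), min(m, m - dy)
    x0, x1 = max(0, -dx), min(n, n - dx)
    src[y0:y1, x0:x1] = True
    valid = src & mask & np.roll(np.roll(mask, -dy, axis=0), -dx, axis=1)
    if not valid.any():
        raise ValueError("no co-occurring pixel pairs inside the mask")

    a = q[valid]
    b = np.roll(np.roll(q, -dy, axis=0), -dx, axis=1)[valid]
    counts = np.zeros((levels, levels))
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    return counts / counts.sum()


def texture_features(p: np.ndarray) -> tuple[float, float, float, float, float]:
    """(contrast, entropy, homogeneity, energy, correlation) of a normalized GLCM."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("co-occurrence matrix must be normalized")
    levels = p.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]

    contrast = float(np.sum((i - j) ** 2 * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    energy = float(np.sum(p * p))

    mu_r = float(np.sum(i * p))
    mu_c = float(np.sum(j * p))
    sig_r = float(np.sqrt(np.sum((i - mu_r) ** 2 * p)))
    sig_c = float(np.sqrt(np.sum((j - mu_c) ** 2 * p)))
    if sig_r == 0.0 or sig_c == 0.0:
        correlation = 0.0
    else:
        correlation = float(np.sum((i - mu_r) * (j - mu_c) * p) / (sig_r * sig_c))
    return contrast, entropy, homogeneity, energy, correlation


def region_geometry(mask: np.ndarray) -> RegionGeometry:
    """Area, exposed-edge perimeter and full ellipse axis lengths of a region."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    area = int(mask.sum())

    # perimeter: each boundary pixel contributes its 4-neighbour background edges
    padded = np.pad(mask, 1)
    perim = 0
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.roll(np.roll(padded, dy, axis=0), dx, axis=1)
        perim += int(np.sum(padded & ~shifted))

    ys, xs = np.nonzero(mask)
    ys = ys.astype(float)
    xs = xs.astype(float)
    myy = ys.var()
    mxx = xs.var()
    mxy = ((ys - ys.mean()) * (xs - xs.mean())).mean()
    common = np.sqrt(max((myy - mxx) ** 2 + 4.0 * mxy**2, 0.0))
    l1 = (myy + mxx + common) / 2.0
    l2 = (myy + mxx - common) / 2.0
    major = 4.0 * np.sqrt(max(l1, 0.0))
    minor = 4.0 * np.sqrt(max(l2, 0.0))
    return RegionGeometry(major_axis=major, minor_axis=minor, perimeter=float(perim), area=area)


def shape_features(
    mask: np.ndarray,
) -> tuple[float, float, float, float, float, float, float, float]:
    """(area, perimeter, rectangularity, elongation, irregularity_index,
    form_factor, eccentricity, hu_phi1) of a binary region."""
    geom = region_geometry(mask)
    a, b = geom.major_axis, geom.minor_axis
    area = float(geom.area)
    perim = geom.perimeter

    if b <= 0.0 or a <= 0.0:
        rectangularity = 0.0
        eccentricity = 1.0
    else:
        rectangularity = area / (a * b)
        eccentricity = float(np.sqrt(max(a * a - b * b, 0.0)) / a)
    elongation = 2.0 * np.sqrt(area / np.pi) / a if a > 0 else 0.0
    irregularity = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
    form_factor = area / (a * a) if a > 0 else 0.0

    # first Hu invariant of the binary region: eta20 + eta02
    m = np.asarray(mask).astype(float)
    ys, xs = np.nonzero(m)
    cy, cx = ys.mean(), xs.mean()
    mu00 = area
    mu20 = float(np.sum((ys - cy) ** 2))
    mu02 = float(np.sum((xs - cx) ** 2))
    hu_phi1 = (mu20 + mu02) / mu00**2

    return (
        area,
        perim,
        float(rectangularity),
        float(elongation),
        float(irregularity),
        float(form_factor),
        float(eccentricity),
        float(hu_phi1),
    )


def extract_all(
    img: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    displacement: tuple[int, int] = (0, 1),
) -> np.ndarray:
    """The 16-entry descriptor vector in :data:`FEATURE_NAMES` order."""
    mean, var, std = intensity_stats(img, mask)
    p = glcm(img, mask, levels=levels, displacement=displacement)
    contrast, entropy, homogeneity, energy, correlation = texture_features(p)
    (
        area,
        perim,
        rectangularity,
        elongation,
        irregularity,
        form_factor,
        eccentricity,
        hu_phi1,
    ) = shape_features(mask)
    vec = np.array(
        [
            mean,
            var,
            std,
            contrast,
            area,
            rectangularity,
            elongation,
            irregularity,
            form_factor,
            eccentricity,
            entropy,
            perim,
            homogeneity,
            energy,
            correlation,
            hu_phi1,
        ]
    )
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value")
    return vec
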