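"""Lesion segmentation: Otsu global thresholding plus binary morphology.

The image is quantized to 256 uniform levels, the threshold maximizing the
between-class variance is chosen (smallest maximizer on ties), the darker
class is taken as the lesion, and hole filling, opening and closing are
applied before keeping the largest connected component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .denoise import validate_image

__all__ = [
    "ThresholdResult",
    "StructuringElement",
    "square_se",
    "identity_se",
    "quantize",
    "otsu_threshold",
    "fill_holes",
    "morph_open",
    "morph_close",
    "largest_component",
    "segment_lesion",
]


class DegenerateHistogramError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdResult:
    t: int
    between_class_variance: np.ndarray  # sigma_b^2 for every candidate t (256,)
    class_probs: np.ndarray  # (256, 2): omega1(t), omega2(t)
    class_means: np.ndarray  # (256, 2): mu1(t), mu2(t)


@dataclass(frozen=True)
class StructuringElement:
    footprint: np.ndarray

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.size == 0 or not fp.any():
            raise ValueError("structuring element must be nonempty")
        if any(s % 2 == 0 for s in fp.shape):
            raise ValueError("structuring element must have odd side lengths")
        object.__setattr__(self, "footprint", fp)


def square_se(size: int = 5) -> StructuringElement:
    return StructuringElement(np.ones((size, size), dtype=bool))


def identity_se(size: int = 5) -> StructuringElement:
    """Diagonal structuring element (the published 'identity matrix' reading)."""
    return StructuringElement(np.eye(size, dtype=bool))


def quantize(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Map [0, 1] intensities to integer levels 0..levels-1 by rounding."""
    img = validate_image(img)
    return np.rint(img * (levels - 1)).astype(np.int64)


def otsu_threshold(img: np.ndarray) -> ThresholdResult:
    """Threshold maximizing the between-class variance of the 256-level histogram.

    Pixels with level <= t form class 1, the rest class 2.  Raises
    :class:`DegenerateHistogramError` for constant images.
    """
    q = quantize(img)
    hist = np.bincount(q.ravel(), minlength=256).astype(float)
    total = hist.sum()
    p = hist / total
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("degenerate histogram")

    levels = np.arange(256, dtype=float)
    omega1 = np.cumsum(p)
    omega2 = 1.0 - omega1
    cum_mean = np.cumsum(p * levels)
    mu_total = cum_mean[-1]

    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = np.where(omega1 > 0, cum_mean / omega1, 0.0)
        mu2 = np.where(omega2 > 0, (mu_total - cum_mean) / omega2, 0.0)
    sigma_b = omega1 * omega2 * (mu1 - mu2) ** 2
    sigma_b = np.where((omega1 > 0) & (omega2 > 0), sigma_b, 0.0)

    t = int(np.argmax(sigma_b))  # argmax returns the smallest maximizer
    return ThresholdResult(
        t=t,
        between_class_variance=sigma_b,
        class_probs=np.stack([omega1, omega2], axis=1),
        class_means=np.stack([mu1, mu2], axis=1),
    )


def _as_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def fill_holes(mask: np.ndarray, e: StructuringElement | None = None) -> np.ndarray:
    """Fill interior holes by growing the border-connected background.

    Iterates X_k = (X_{k-1} dilated by e) intersected with the mask
    complement, seeded from the border, until a fixpoint; the output is
    the complement of the reached background.  ``e`` defaults to the
    elementary 3x3 cross (4-connected growth), which cannot jump across
    thin walls and therefore agrees with a border flood fill; larger
    elements are accepted but can leak through walls thinner than their
    radius.
    """
    mask = _as_mask(mask)
    fp = (
        ndimage.generate_binary_structure(2, 1) if e is None else e.footprint
    )
    comp = ~mask
    seed = np.zeros_like(mask)
    seed[0, :] = comp[0, :]
    seed[-1, :] = comp[-1, :]
    seed[:, 0] = comp[:, 0]
    seed[:, -1] = comp[:, -1]
    x = seed
    while True:
        grown = ndimage.binary_dilation(x, structure=fp) & comp
        if np.array_equal(grown, x):
            break
        x = grown
    return (~x).astype(np.uint8)


def morph_open(mask: np.ndarray, e: StructuringElement) -> np.ndarray:
    """Erosion followed by dilation with the same element (anti-extensive)."""
    mask = _as_mask(mask)
    eroded = ndimage.binary_erosion(mask, structure=e.footprint)
    return ndimage.binary_dilation(eroded, structure=e.footprint).astype(np.uint8)


def morph_close(mask: np.ndarray, e: StructuringElement) -> np.ndarray:
    """Dilation followed by erosion with the same element (extensive).

    The dilated mask is padded virtually (border_value=0 for dilation,
    1 for the following erosion) so closing never eats the true border.
    """
    mask = _as_mask(mask)
    dilated = ndimage.binary_dilation(mask, structure=e.footprint)
    return ndimage.binary_erosion(
        dilated, structure=e.footprint, border_value=1
    ).astype(np.uint8)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component."""
    mask = _as_mask(mask)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        raise ValueError("no lesion found")
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return (labels == keep).astype(np.uint8)


def segment_lesion(img: np.ndarray, e: StructuringElement | None = None) -> np.ndarray:
    """Full segmentation: Otsu, dark class as lesion, fill/open/close, largest blob."""
    if e is None:
        e = square_se(5)
    res = otsu_threshold(img)
    q = quantize(img)
    # lesion = lower-mean class; with the <=t convention class 1 is always darker
    mask = (q <= res.t).astype(np.uint8)
    mask = fill_holes(mask)
    mask = morph_open(mask, e)
    if not mask.any():
        raise ValueError("no lesion found")
    mask = morph_close(mask, e)
    return largest_component(mask)
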