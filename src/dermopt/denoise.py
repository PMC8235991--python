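"""Non-local means denoising.

Pixels are restored as convex combinations of the pixels in a search
window, weighted by the Gaussian-kernel-weighted Euclidean distance
between the surrounding patches.  Images are 2-D float arrays with
intensities in [0, 1]; borders are reflect-padded, so candidate patches
near the edge are built from mirrored pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["DenoiseParams", "validate_image", "gaussian_patch_kernel", "patch_distance", "nlm_filter"]


@dataclass(frozen=True)
class DenoiseParams:
    h: float = 0.1
    search_radius: int = 10
    sim_radius: int = 3
    kernel_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if not (self.search_radius >= self.sim_radius >= 1):
            raise ValueError("require search_radius >= sim_radius >= 1")
        if self.kernel_sigma <= 0:
            raise ValueError("kernel_sigma must be > 0")


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check a 2-D intensity grid: finite values, range [0, 1]."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("intensities must lie in [0, 1]")
    return img


def gaussian_patch_kernel(sim_radius: int, sigma: float) -> np.ndarray:
    """Normalized isotropic Gaussian over a (2r+1)^2 patch, centred."""
    ax = np.arange(-sim_radius, sim_radius + 1, dtype=float)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))
    return k / k.sum()


def patch_distance(
    img: np.ndarray, i: tuple[int, int], j: tuple[int, int], params: DenoiseParams
) -> float:
    """Gaussian-weighted squared distance between the patches at pixels i and j."""
    img = validate_image(img)
    r = params.sim_radius
    padded = np.pad(img, r, mode="reflect")
    kernel = gaussian_patch_kernel(r, params.kernel_sigma)

    def patch(center: tuple[int, int]) -> np.ndarray:
        y, x = center[0] + r, center[1] + r
        return padded[y - r : y + r + 1, x - r : x + r + 1]

    diff = patch(i) - patch(j)
    return float(np.sum(kernel * diff * diff))


def nlm_filter(img: np.ndarray, params: DenoiseParams | None = None) -> np.ndarray:
    """Filter every pixel by patch-similarity weighted averaging.

    For each pixel, weights w = exp(-d/h^2) are computed against every
    candidate in the (2*search_radius+1)^2 window (the pixel itself
    included with its literal zero distance), normalized to sum one, and
    the output is the weighted average of the candidate pixels.
    """
    if params is None:
        params = DenoiseParams()
    img = validate_image(img)
    m, n = img.shape
    big_r, r = params.search_radius, params.sim_radius
    pad = big_r + r
    padded = np.pad(img, pad, mode="reflect")
    kernel = gaussian_patch_kernel(r, params.kernel_sigma)
    h2 = params.h * params.h

    num = np.zeros((m, n))
    den = np.zeros((m, n))
    for oy in range(-big_r, big_r + 1):
        for ox in range(-big_r, big_r + 1):
            a = padded[pad - r : pad + m + r, pad - r : pad + n + r]
            b = padded[pad - r + oy : pad + m + r + oy, pad - r + ox : pad + n + r + ox]
            sq = (a - b) ** 2
            dist = ndimage.correlate(sq, kernel, mode="constant")[r : r + m, r : r + n]
            w = np.exp(-dist / h2)
            vals = padded[pad + oy : pad + m + oy, pad + ox : pad + n + ox]
            num += w * vals
            den += w
    return num / den
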