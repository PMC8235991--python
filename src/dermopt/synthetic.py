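"""Synthetic dermoscopy-like fixtures.

Renders dark, roughly elliptical pigmented lesions on a brighter mottled
background, with optional hair-like curvilinear clutter and additive
Gaussian noise, together with exact ground-truth masks and class labels.
"Cancerous" lesions get an irregular, radially perturbed, more eccentric
boundary; "healthy" nevi are rounder and smoother.  Also generates
tabular datasets with planted informative columns for selection tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

from .classify import NEGATIVE, POSITIVE, LabeledDataset

__all__ = [
    "SynthConfig",
    "SyntheticSample",
    "PlantedTabularDataset",
    "PRESETS",
    "gen_image",
    "gen_cohort",
    "gen_tabular",
]


@dataclass(frozen=True)
class SynthConfig:
    size: int = 256
    bg_mean: float = 0.75
    lesion_mean: float = 0.25
    mottle_amp: float = 0.04
    mottle_scale: float = 24.0
    noise_sigma: float = 0.02
    n_hairs: int = 0
    hair_intensity: float = 0.15
    radius_range: tuple[float, float] = (40.0, 65.0)
    # axis ratio (minor/major) ranges per class
    ratio_healthy: tuple[float, float] = (0.85, 1.0)
    ratio_cancerous: tuple[float, float] = (0.45, 0.7)
    # radial boundary perturbation amplitude per class
    wobble_healthy: float = 0.03
    wobble_cancerous: float = 0.22
    wobble_harmonics: tuple[int, ...] = (3, 4, 5, 6, 7, 8)


PRESETS: dict[str, SynthConfig] = {
    "easy": SynthConfig(noise_sigma=0.02, n_hairs=0),
    "hard": SynthConfig(noise_sigma=0.12, n_hairs=6, mottle_amp=0.08),
}


@dataclass
class SyntheticSample:
    image: np.ndarray
    truth_mask: np.ndarray
    label: str
    params: dict


@dataclass
class PlantedTabularDataset:
    data: LabeledDataset
    informative: tuple[int, ...]
    effect: float


def _mottle(size: int, scale: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Low-frequency multiplicative-free texture field in [-amp, amp]."""
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=scale)
    span = np.abs(smooth).max()
    if span == 0:
        return np.zeros((size, size))
    return amp * smooth / span


def _lesion_mask(size: int, cfg: SynthConfig, label: str, rng: np.random.Generator) -> np.ndarray:
    center = size / 2.0 + rng.uniform(-15, 15, size=2)
    radius = rng.uniform(*cfg.radius_range)
    lo, hi = cfg.ratio_cancerous if label == POSITIVE else cfg.ratio_healthy
    ratio = rng.uniform(lo, hi)
    theta = rng.uniform(0, np.pi)
    amp = cfg.wobble_cancerous if label == POSITIVE else cfg.wobble_healthy
    coeffs = rng.uniform(-1, 1, size=len(cfg.wobble_harmonics))
    phases = rng.uniform(0, 2 * np.pi, size=len(cfg.wobble_harmonics))

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    # rotate into the ellipse frame and squash the minor axis
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    rad = np.hypot(u, v / ratio)
    phi = np.arctan2(v / ratio, u)
    boundary = np.ones_like(phi)
    norm = np.sqrt(len(cfg.wobble_harmonics))
    for h, a, ps in zip(cfg.wobble_harmonics, coeffs, phases):
        boundary += amp * a * np.cos(h * phi + ps) / norm
    return (rad <= radius * boundary).astype(np.uint8)


def _draw_hairs(img: np.ndarray, n: int, intensity: float, rng: np.random.Generator) -> None:
    size = img.shape[0]
    for _ in range(n):
        p0 = rng.uniform(0, size, 2)
        p1 = rng.uniform(0, size, 2)
        ctrl = (p0 + p1) / 2 + rng.uniform(-size / 3, size / 3, 2)
        t = np.linspace(0, 1, 4 * size)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * ctrl + t**2 * p1
        ys = np.clip(np.rint(pts[:, 0]).astype(int), 0, size - 1)
        xs = np.clip(np.rint(pts[:, 1]).astype(int), 0, size - 1)
        img[ys, xs] = intensity
        img[np.clip(ys + 1, 0, size - 1), xs] = intensity


def gen_image(
    label: str, seed: int, cfg: SynthConfig | None = None
) -> SyntheticSample:
    """Render one lesion-on-skin sample with its exact ground-truth mask."""
    if cfg is None:
        cfg = PRESETS["easy"]
    if label not in (POSITIVE, NEGATIVE):
        raise ValueError(f"label must be {POSITIVE!r} or {NEGATIVE!r}")
    rng = np.random.default_rng(seed)
    size = cfg.size

    img = cfg.bg_mean + _mottle(size, cfg.mottle_scale, cfg.mottle_amp, rng)
    mask = _lesion_mask(size, cfg, label, rng)
    lesion_tex = _mottle(size, cfg.mottle_scale / 2, cfg.mottle_amp / 2, rng)
    img = np.where(mask, cfg.lesion_mean + lesion_tex, img)
    if cfg.n_hairs:
        _draw_hairs(img, cfg.n_hairs, cfg.hair_intensity, rng)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0, cfg.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0)

    params = {"label": label, "seed": int(seed), **asdict(cfg)}
    return SyntheticSample(image=img, truth_mask=mask, label=label, params=params)


def gen_cohort(
    n: int, preset: str | SynthConfig = "easy", seed: int = 0
) -> list[SyntheticSample]:
    """Balanced cohort of n samples (alternating labels, derived seeds)."""
    cfg = PRESETS[preset] if isinstance(preset, str) else preset
    seeds = np.random.SeedSequence(seed).generate_state(n)
    return [
        gen_image(POSITIVE if i % 2 == 0 else NEGATIVE, int(seeds[i]), cfg)
        for i in range(n)
    ]


def gen_tabular(
    n: int,
    d: int,
    informative: Sequence[int],
    effect: float,
    seed: int = 0,
) -> PlantedTabularDataset:
    """Balanced two-class dataset: N(0,1) noise columns, informative columns
    shifted by ``effect`` in the cancerous class."""
    if n < 4:
        raise ValueError("n must be >= 4")
    informative = tuple(int(i) for i in informative)
    if any(i < 0 or i >= d for i in informative):
        raise ValueError("informative indices out of range")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, d))
    labels = np.array([POSITIVE, NEGATIVE] * ((n + 1) // 2))[:n]
    rng.shuffle(labels)
    x[np.ix_(labels == POSITIVE, informative)] += effect
    return PlantedTabularDataset(
        data=LabeledDataset(x, labels), informative=informative, effect=effect
    )
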