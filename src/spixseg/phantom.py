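"""Synthetic multimodal slice phantoms with focal bright lesions.

The generator emulates the statistics the pipeline is sensitive to, without
any anatomy: a smooth textured "brain" disk on a zero background, four
correlated channels (a shared low-frequency field plus channel-specific
variation, mimicking multimodal redundancy), and an optional focal lesion
built as a union of 1–3 overlapping ellipses whose additive contrast is
largest on channel 4 (the FLAIR-like channel, where edema/tumor appears
bright).  Reference masks record the lesion support and are used only for
evaluation; image-level labels are 1 exactly when the mask is non-empty.

Lesion unions (rather than single circles) give superpixel boundaries
something nontrivial to refine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import MultimodalSlice

#: additive per-channel lesion offsets at the default difficulty
DEFAULT_CONTRAST = (0.15, 0.25, 0.3, 0.5)


@dataclass
class PhantomConfig:
    n_images: int = 256
    image_size: tuple[int, int] = (32, 32)
    lesion_prevalence: float = 0.7
    lesion_radius_range: tuple[float, float] | None = None  # px; None -> scaled
    lesion_contrast: tuple[float, float, float, float] = DEFAULT_CONTRAST
    background_texture_scale: float = 8.0  # px per texture cell
    noise_sd: float = 0.03
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lesion_prevalence <= 1.0:
            raise ValueError("lesion_prevalence must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.lesion_radius_range is None:
            # reference radii (8, 16) at a 128-px image, scaled linearly
            s = min(self.image_size) / 128.0
            self.lesion_radius_range = (8.0 * s, 16.0 * s)
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi < min(self.image_size) / 2):
            raise ValueError(
                f"lesion_radius_range {self.lesion_radius_range} must be positive "
                f"and below min(H, W)/2"
            )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  cell: float) -> np.ndarray:
    """Low-frequency random field in [0, 1], smoothness set by ``cell`` px."""
    h, w = shape
    coarse = rng.standard_normal((max(2, int(np.ceil(h / cell)) + 1),
                                  max(2, int(np.ceil(w / cell)) + 1)))
    zoom = (h / coarse.shape[0], w / coarse.shape[1])
    f = ndimage.zoom(coarse, zoom, order=3)[:h, :w]
    f -= f.min()
    rng_span = f.max() - f.min()
    return f / rng_span if rng_span > 0 else np.zeros_like(f)


def _ellipse_support(shape: tuple[int, int], center: tuple[float, float],
                     semi_axes: tuple[float, float], angle: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return (u / semi_axes[1]) ** 2 + (v / semi_axes[0]) ** 2 <= 1.0


def _lesion_mask(rng: np.random.Generator, shape: tuple[int, int],
                 brain: np.ndarray, radius_range: tuple[float, float]) -> np.ndarray:
    """Union of 1–3 overlapping ellipses centred inside the brain disk."""
    h, w = shape
    cy = h / 2 + rng.uniform(-0.25, 0.25) * h
    cx = w / 2 + rng.uniform(-0.25, 0.25) * w
    mask = np.zeros(shape, dtype=bool)
    for _ in range(int(rng.integers(1, 4))):
        jitter = max(1.0, 0.3 * radius_range[0])
        ey = cy + rng.uniform(-jitter, jitter)
        ex = cx + rng.uniform(-jitter, jitter)
        axes = (rng.uniform(*radius_range), rng.uniform(*radius_range))
        mask |= _ellipse_support(shape, (ey, ex), axes, rng.uniform(0, np.pi))
    mask &= brain
    if not mask.any():  # ellipse fell outside the brain; anchor a minimal core
        mask[int(np.clip(cy, 0, h - 1)), int(np.clip(cx, 0, w - 1))] = True
        mask &= brain
        if not mask.any():
            mask[h // 2, w // 2] = True
    return mask


def generate_phantom(config: PhantomConfig) -> list[MultimodalSlice]:
    """Generate a deterministic phantom dataset from ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_size
    yy, xx = np.mgrid[0:h, 0:w]
    brain = (
        ((yy - h / 2) / (0.46 * h)) ** 2 + ((xx - w / 2) / (0.46 * w)) ** 2
    ) <= 1.0
    out: list[MultimodalSlice] = []
    for i in range(config.n_images):
        shared = _smooth_field(rng, (h, w), config.background_texture_scale)
        channels = np.zeros((4, h, w), dtype=np.float32)
        for c in range(4):
            own = _smooth_field(rng, (h, w), config.background_texture_scale)
            tex = 0.7 * shared + 0.3 * own  # correlated modalities
            channels[c] = (0.3 + 0.4 * tex) * brain
        has_lesion = rng.random() < config.lesion_prevalence
        if has_lesion:
            mask = _lesion_mask(rng, (h, w), brain, config.lesion_radius_range)
            for c in range(4):
                channels[c][mask] += config.lesion_contrast[c]
        else:
            mask = np.zeros((h, w), dtype=bool)
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=channels.shape)
            channels += (noise * brain).astype(np.float32)
        # fixed intensity scale, clipped to [0, 1]: mirrors volume-level
        # normalisation, where one slice's lesion cannot rescale its own
        # background (a per-image rescale would turn background brightness
        # into a global tumor shortcut no real classifier could rely on)
        np.clip(channels, 0.0, 1.0, out=channels)
        out.append(
            MultimodalSlice(
                pixels=channels,
                label=int(mask.any()),
                reference_mask=mask.astype(np.uint8),
                patient_id=f"phantom{i:05d}",
                slice_index=0,
            )
        )
    return out


def phantom_difficulty_suite(
    n_images: int = 256, image_size: tuple[int, int] = (32, 32)
) -> dict[str, PhantomConfig]:
    """Named difficulty settings used throughout tests and examples.

    Radii are stated at a 128-px reference scale and scaled linearly to
    ``image_size``; "easy" pairs large lesions with channel-4 contrast well
    above the noise floor, "hard" shrinks and dims them, and "healthy_only"
    contains no lesions at all.
    """
    s = min(image_size) / 128.0
    return {
        "easy": PhantomConfig(
            n_images=n_images,
            image_size=image_size,
            lesion_prevalence=0.7,
            lesion_radius_range=(20.0 * s, 36.0 * s),
            lesion_contrast=(0.3, 0.4, 0.5, 0.8),
            noise_sd=0.03,
            rng_seed=11,
        ),
        "hard": PhantomConfig(
            n_images=n_images,
            image_size=image_size,
            lesion_prevalence=0.7,
            lesion_radius_range=(max(1.0, 6.0 * s), max(1.5, 12.0 * s)),
            lesion_contrast=(0.05, 0.08, 0.1, 0.15),
            noise_sd=0.08,
            rng_seed=13,
        ),
        "healthy_only": PhantomConfig(
            n_images=n_images,
            image_size=image_size,
            lesion_prevalence=0.0,
            rng_seed=17,
        ),
    }
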