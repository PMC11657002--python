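"""Stage 2: occlusion-saliency seeds from the classifier (RISE).

Randomized Input Sampling for Explanation: perturb the input with many
random soft masks, score each perturbed image with the classifier, and
accumulate score-weighted masks into a per-pixel saliency heatmap

    H(p) = (1 / (K * keep_prob)) * sum_i score_i * mask_i(p).

Masks follow the canonical construction: a coarse s×s Bernoulli(keep_prob)
grid, bilinearly upsampled to slightly larger than the image, then randomly
shifted and cropped — yielding smooth occlusion patterns.  One mask set is
generated once and reused across every image.

Heatmaps become ternary localization seeds by rank: the top 20% of pixels
are positive seeds (high tumor likelihood), the bottom 20% negative seeds,
the middle 60% unseeded.  Images the classifier calls healthy get their
seeds replaced by an all-negative map, so inaccurate positive seeds on
healthy images cannot propagate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .classifier import TrainedClassifier, predict_batch


@dataclass
class MaskSet:
    """K soft occlusion masks in [0, 1], shared across all images."""

    masks: np.ndarray  # (K, H, W)
    cell_grid: int
    keep_prob: float
    rng_seed: int

    def __post_init__(self):
        if self.masks.ndim != 3:
            raise ValueError("masks must be (K, H, W)")
        if self.masks.min() < 0 or self.masks.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")


@dataclass
class SeedMap:
    """Disjoint positive / negative binary seed maps; the rest is unseeded."""

    positive: np.ndarray
    negative: np.ndarray

    def __post_init__(self):
        self.positive = np.asarray(self.positive, dtype=bool)
        self.negative = np.asarray(self.negative, dtype=bool)
        if self.positive.shape != self.negative.shape:
            raise ValueError("positive/negative shape mismatch")
        if np.logical_and(self.positive, self.negative).any():
            raise ValueError("positive and negative seeds must be disjoint")

    @property
    def unseeded(self) -> np.ndarray:
        return ~(self.positive | self.negative)


def generate_masks(
    K: int = 4000,
    cell_grid: int = 8,
    keep_prob: float = 0.5,
    image_shape: tuple[int, int] = (128, 128),
    rng_seed: int = 0,
) -> MaskSet:
    """Draw K random occlusion masks (deterministic per seed)."""
    if K <= 0:
        raise ValueError("K must be positive")
    if not 0.0 < keep_prob < 1.0:
        raise ValueError("keep_prob must be strictly inside (0, 1): 0 or 1 "
                         "would make every mask uninformative")
    rng = np.random.default_rng(rng_seed)
    h, w = image_shape
    cell_h, cell_w = int(np.ceil(h / cell_grid)), int(np.ceil(w / cell_grid))
    up_h, up_w = (cell_grid + 1) * cell_h, (cell_grid + 1) * cell_w
    masks = np.empty((K, h, w), dtype=np.float32)
    for i in range(K):
        grid = (rng.random((cell_grid, cell_grid)) < keep_prob).astype(np.float32)
        big = ndimage.zoom(grid, (up_h / cell_grid, up_w / cell_grid), order=1)
        dy = int(rng.integers(0, cell_h))
        dx = int(rng.integers(0, cell_w))
        masks[i] = big[dy : dy + h, dx : dx + w]
    np.clip(masks, 0.0, 1.0, out=masks)
    return MaskSet(masks=masks, cell_grid=cell_grid, keep_prob=keep_prob,
                   rng_seed=rng_seed)


def rise_heatmap(
    model: TrainedClassifier,
    image,
    masks: MaskSet,
    batch_size: int = 128,
    score_fn=None,
) -> np.ndarray:
    """Saliency heatmap for one image: score-weighted mask average.

    Masks multiply intensities on all 4 channels (occlusion towards 0).
    ``score_fn`` (a callable (B,4,H,W) -> (B,) of scores) replaces the
    classifier when probing with analytic toy models.
    """
    from .classifier import _pixels  # noqa: PLC0415 - avoid cycle at import

    pixels = _pixels(image)
    h, w = pixels.shape[-2:]
    if masks.masks.shape[1:] != (h, w):
        raise ValueError(
            f"mask shape {masks.masks.shape[1:]} does not match image ({h}, {w})"
        )
    K = len(masks.masks)
    scores = np.empty(K, dtype=np.float64)
    for start in range(0, K, batch_size):
        chunk = masks.masks[start : start + batch_size]
        perturbed = pixels[None, :, :, :] * chunk[:, None, :, :]
        if score_fn is not None:
            s = np.asarray(score_fn(perturbed), dtype=np.float64)
        else:
            s = predict_batch(model, perturbed)
        if not np.all(np.isfinite(s)):
            raise RuntimeError("classifier produced non-finite scores on masked input")
        scores[start : start + len(chunk)] = s
    heat = np.tensordot(scores, masks.masks.astype(np.float64), axes=([0], [0]))
    return heat / (K * masks.keep_prob)


def seeds_from_heatmap(heatmap: np.ndarray, quantile: float = 0.2) -> SeedMap:
    """Ternary seeds by rank: top ``quantile`` positive, bottom ``quantile`` negative.

    Exactly ``round(quantile * H * W)`` pixels land in each class.  Ties are
    broken by stable raster order (ascending stable argsort: the negative
    seeds take the earliest raster positions among tied low values, the
    positive seeds the latest among tied high values).
    """
    heatmap = np.asarray(heatmap)
    if not np.all(np.isfinite(heatmap)):
        raise ValueError("heatmap contains non-finite values")
    n_pixels = heatmap.size
    if n_pixels < 10:
        raise ValueError("heatmap too small for quantile seeding (need >= 10 px)")
    n_seed = int(round(quantile * n_pixels))
    order = np.argsort(heatmap.ravel(), kind="stable")
    positive = np.zeros(n_pixels, dtype=bool)
    negative = np.zeros(n_pixels, dtype=bool)
    negative[order[:n_seed]] = True
    positive[order[n_pixels - n_seed :]] = True
    return SeedMap(
        positive=positive.reshape(heatmap.shape),
        negative=negative.reshape(heatmap.shape),
    )


def apply_healthy_override(seedmap: SeedMap, predicted_label: int) -> SeedMap:
    """All pixels become negative seeds when the classifier predicts healthy."""
    if predicted_label not in (0, 1):
        raise ValueError("predicted_label must be 0 or 1")
    if predicted_label == 1:
        return seedmap
    shape = seedmap.positive.shape
    return SeedMap(
        positive=np.zeros(shape, dtype=bool),
        negative=np.ones(shape, dtype=bool),
    )


def seeds_for_dataset(
    model: TrainedClassifier,
    slices,
    masks: MaskSet,
    quantile: float = 0.2,
    batch_size: int = 128,
) -> list[SeedMap]:
    """Stage-2 convenience: heatmap -> seeds -> healthy override per image."""
    out = []
    for sl in slices:
        heat = rise_heatmap(model, sl, masks, batch_size=batch_size)
        seeds = seeds_from_heatmap(heat, quantile=quantile)
        from .classifier import classify

        out.append(apply_healthy_override(seeds, classify(model, sl)))
    return out


def save_seed_maps(seed_maps: list[SeedMap], path) -> None:
    pos = np.stack([s.positive for s in seed_maps]).astype(np.uint8)
    neg = np.stack([s.negative for s in seed_maps]).astype(np.uint8)
    np.savez_compressed(path, positive=pos, negative=neg)


def load_seed_maps(path) -> list[SeedMap]:
    with np.load(path) as data:
        pos, neg = data["positive"], data["negative"]
    return [SeedMap(positive=p, negative=n) for p, n in zip(pos, neg)]
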