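"""QC figures: seed overlays and superpixel label maps."""

from __future__ import annotations

import numpy as np

from .rise import SeedMap


def seed_overlay(image_channel: np.ndarray, seeds: SeedMap) -> np.ndarray:
    """RGB overlay: green = positive seeds, magenta = negative, gray elsewhere."""
    g = np.clip(np.asarray(image_channel, dtype=float), 0, 1)
    rgb = np.stack([g, g, g], axis=-1)
    rgb[seeds.positive] = [0.0, 0.9, 0.2]
    rgb[seeds.negative] = 0.6 * rgb[seeds.negative] + 0.4 * np.array([1.0, 0.0, 1.0])
    return rgb


def save_seed_overlay(path, image_channel: np.ndarray, seeds: SeedMap) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(seed_overlay(image_channel, seeds), interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)


def hard_superpixel_labels(q: np.ndarray) -> np.ndarray:
    """Argmax label map (H, W) from an (N_S, H, W) association map."""
    return np.argmax(np.asarray(q), axis=0).astype(np.uint8)
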