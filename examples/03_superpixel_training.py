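"""Jointly train the superpixel generator and clusterer from seeds alone.

Uses ground-truth-free supervision: each slice's seeds (here built directly
from a toy saliency rule for brevity) drive the seeding loss while the
compactness/intensity loss shapes the superpixels.  Prints the loss
trajectory and the number of effective superpixels (candidates that actually
own pixels) — typically far fewer than the N_S = 64 available.
"""

import numpy as np

from spixseg import count_effective_superpixels, generate_phantom, phantom_difficulty_suite
from spixseg.pipeline import SuperpixelTrainConfig, train_superpixel_stage
from spixseg.rise import SeedMap

suite = phantom_difficulty_suite(n_images=48, image_size=(32, 32))
slices = generate_phantom(suite["easy"])

# stand-in seeds from the reference masks, eroded/dilated to mimic the
# undersegmentation property of saliency seeds (real runs use the classifier)
from scipy import ndimage

seeds = []
for s in slices:
    mask = s.reference_mask.astype(bool)
    pos = ndimage.binary_erosion(mask, iterations=1) if s.label else np.zeros_like(mask)
    neg = ~ndimage.binary_dilation(mask, iterations=3) if s.label else np.ones_like(mask)
    seeds.append(SeedMap(positive=pos, negative=neg & ~pos))

gen, clu, history = train_superpixel_stage(
    slices, seeds,
    SuperpixelTrainConfig(n_superpixels=32, base_channels=8, epochs=8,
                          batch_size=16, lr=1e-3, weight_decay=0.01, rng_seed=0),
)
print(history[["epoch", "loss", "spixel_loss", "seed_loss"]].round(3).to_string(index=False))
eff = [count_effective_superpixels(gen.associations(s)) for s in slices[:16]]
print(f"effective superpixels: {np.mean(eff):.1f} of 32 available")
# The combined loss should fall across epochs; the effective count shows the
# soft associations collapsing onto a handful of used superpixels.
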