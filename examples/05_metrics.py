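"""The evaluation conventions on small hand-built masks.

Demonstrates smoothed Dice, undersegmented Dice (U-Dice) and directed HD95,
including the empty-mask conventions that matter when a classifier gate
forces empty segmentations.
"""

import numpy as np

from spixseg import dice, hd95, u_dice

truth = np.zeros((16, 16), dtype=bool)
truth[4:12, 4:12] = True            # 8×8 reference lesion

inside = np.zeros_like(truth)
inside[6:10, 6:10] = True           # undersegmenting prediction
shifted = np.roll(truth, 3, axis=1) # misplaced prediction
empty = np.zeros_like(truth)

for name, pred in [("inside", inside), ("shifted", shifted), ("empty", empty)]:
    print(f"{name:>8}: dice={dice(pred, truth):.3f} "
          f"u_dice={u_dice(pred, truth):.3f} hd95={hd95(pred, truth):.2f}")
print(f"{'both empty':>8}: dice={dice(empty, empty):.3f} hd95={hd95(empty, empty):.2f}")
# "inside" scores u_dice 1.0 (perfect undersegmentation) but dice < 1;
# "empty" vs a real lesion scores u_dice 0; two empty masks score dice 1 by
# the smoothing convention and hd95 0 by the empty-mask rule.
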