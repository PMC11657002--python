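"""Turning soft superpixel clusters into binary tumor segmentations.

The soft clustering heatmap H+(p) = Σ_s q[s, p]·r[s] is a convex combination
of the superpixel scores, so it lives in [0, 1] by construction.  The final
mask thresholds H+ at a level chosen on the validation cohort: the grid
{0.1, …, 0.9} is scanned and the threshold maximising mean validation Dice
is kept (ties resolve to the larger threshold, favouring less-segmented
output).  Note this selection reads validation reference masks — a weak-
supervision leak inherited from the original protocol; ``fixed_threshold``
offers an unsupervised fallback of 0.5.

At inference, any image the classifier calls healthy is assigned an empty
mask regardless of its heatmap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import TrainedClassifier, classify
from .metrics import dice
from .models import SuperpixelClusterer, SuperpixelGenerator

FIXED_FALLBACK_THRESHOLD = 0.5


@dataclass
class Segmentation:
    mask: np.ndarray          # (H, W) binary
    threshold_used: float
    classifier_gate: int      # 0 -> forced-empty healthy override

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.classifier_gate == 0 and self.mask.any():
            raise ValueError("gated-healthy segmentation must be empty")


def soft_cluster_heatmap(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """H+(p) = Σ_s q[s, p]·r[s] for one image (numpy, shape (H, W))."""
    q, r = np.asarray(q), np.asarray(r)
    if q.shape[0] != r.shape[0]:
        raise ValueError(f"N_S mismatch: q has {q.shape[0]}, r has {r.shape[0]}")
    return np.tensordot(r, q, axes=([0], [0]))


def predict_heatmap(
    image, generator: SuperpixelGenerator, clusterer: SuperpixelClusterer
) -> np.ndarray:
    """Run both stage-3 models on one slice and soft-cluster the result."""
    q = generator.associations(image)
    r = clusterer.scores(image, q)
    return soft_cluster_heatmap(q, r)


def select_threshold(
    heatmaps: list[np.ndarray],
    reference_masks: list[np.ndarray],
    grid_step: float = 0.1,
) -> float:
    """Grid-search the binarisation threshold on validation Dice.

    Scans thresholds ``grid_step, 2·grid_step, …, < 1`` and returns the one
    maximising mean per-image Dice; ties break toward the larger threshold.
    """
    if len(heatmaps) == 0:
        raise ValueError("empty validation set: cannot select a threshold")
    if len(heatmaps) != len(reference_masks):
        raise ValueError("heatmaps and reference masks differ in length")
    grid = np.arange(grid_step, 1.0 - 1e-9, grid_step)
    best_t, best_score = grid[0], -np.inf
    for t in grid:
        score = float(
            np.mean(
                [dice(h >= t, m) for h, m in zip(heatmaps, reference_masks)]
            )
        )
        if score >= best_score:  # >= favours the larger threshold on ties
            best_score, best_t = score, float(t)
    return round(best_t, 10)


def fixed_threshold() -> float:
    """Unsupervised fallback when no validation masks are available."""
    return FIXED_FALLBACK_THRESHOLD


def segment(
    image,
    generator: SuperpixelGenerator,
    clusterer: SuperpixelClusterer,
    threshold: float,
    classifier: TrainedClassifier | None = None,
) -> Segmentation:
    """Final mask: empty if the classifier predicts healthy, else {H+ >= t}."""
    gate = 1 if classifier is None else classify(classifier, image)
    if gate == 0:
        from .classifier import _pixels

        shape = _pixels(image).shape[-2:]
        return Segmentation(
            mask=np.zeros(shape, dtype=bool), threshold_used=threshold,
            classifier_gate=0,
        )
    heat = predict_heatmap(image, generator, clusterer)
    return Segmentation(mask=heat >= threshold, threshold_used=threshold,
                        classifier_gate=1)
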