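"""Segmentation evaluation: smoothed Dice, undersegmented Dice, and HD95.

Conventions (fixed for reproducibility, and matching how weak-supervision
seeds are meant to be scored):

* Dice uses a smoothing factor of 1 in numerator and denominator, so two
  empty masks score 1.
* U-Dice (undersegmented Dice) measures how much of mask A lies inside the
  reference B: ``(|A∩B|+1)/(|A|+1)``, except 0 when A is empty but B is not.
  It is deliberately asymmetric — A ⊆ B always scores 1.
* HD95 is the 95th percentile (linear interpolation) of the directed
  Euclidean distances from each boundary pixel of A to the nearest boundary
  pixel of B.  Boundary pixels are mask pixels with at least one non-mask
  4-neighbour (image edges count as outside).  Either mask empty -> 0.
  Distances are in pixel units.  A symmetric variant is available via
  ``symmetric=True``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    return mask.astype(bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")


def dice(a: np.ndarray, b: np.ndarray, smooth: float = 1.0) -> float:
    """Smoothed Dice overlap: (2|A∩B| + s) / (|A| + |B| + s)."""
    a, b = _as_binary(a), _as_binary(b)
    _check_shapes(a, b)
    inter = np.logical_and(a, b).sum()
    return float((2.0 * inter + smooth) / (a.sum() + b.sum() + smooth))


def u_dice(a: np.ndarray, b: np.ndarray, smooth: float = 1.0) -> float:
    """Undersegmented Dice: fraction of A inside B, smoothed; 0 if A empty, B not."""
    a, b = _as_binary(a), _as_binary(b)
    _check_shapes(a, b)
    na = a.sum()
    if na == 0 and b.sum() > 0:
        return 0.0
    inter = np.logical_and(a, b).sum()
    return float((inter + smooth) / (na + smooth))


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with >= 1 non-mask 4-neighbour; image edges count as outside."""
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~interior


def hd95(a: np.ndarray, b: np.ndarray, symmetric: bool = False) -> float:
    """95th-percentile boundary distance from A to B (directed by default)."""
    a, b = _as_binary(a), _as_binary(b)
    _check_shapes(a, b)
    if not a.any() or not b.any():
        return 0.0
    ba, bb = _boundary(a), _boundary(b)
    # exact Euclidean distance to the nearest B-boundary pixel, sampled on A's
    dist_to_b = ndimage.distance_transform_edt(~bb)
    d_ab = dist_to_b[ba]
    if not symmetric:
        return float(np.percentile(d_ab, 95))
    dist_to_a = ndimage.distance_transform_edt(~ba)
    d_ba = dist_to_a[bb]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def evaluate_cohort(
    segmentations: list[np.ndarray],
    references: list[np.ndarray],
    classifier_correct: list[bool] | None = None,
    ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-image Dice / HD95 / U-Dice with cohort means.

    Returns a table with one row per image plus summary rows ``mean_all`` and,
    when classifier correctness flags are given, ``mean_correct`` /
    ``mean_incorrect`` (mirroring evaluation stratified by whether the
    image-level classifier got each image right).
    """
    if len(segmentations) != len(references):
        raise ValueError("segmentations and references differ in length")
    n = len(segmentations)
    ids = ids if ids is not None else [str(i) for i in range(n)]
    correct = classifier_correct if classifier_correct is not None else [True] * n
    rows = []
    for i in range(n):
        rows.append(
            {
                "id": ids[i],
                "dice": dice(segmentations[i], references[i]),
                "hd95": hd95(segmentations[i], references[i]),
                "u_dice": u_dice(segmentations[i], references[i]),
                "classifier_correct": bool(correct[i]),
            }
        )
    table = pd.DataFrame(rows)
    summaries = [_summary_row(table, "mean_all")]
    if classifier_correct is not None:
        summaries.append(_summary_row(table[table.classifier_correct], "mean_correct"))
        summaries.append(_summary_row(table[~table.classifier_correct], "mean_incorrect"))
    return pd.concat([table, pd.DataFrame(summaries)], ignore_index=True)


def _summary_row(table: pd.DataFrame, name: str) -> dict:
    if len(table) == 0:
        return {"id": name, "dice": np.nan, "hd95": np.nan, "u_dice": np.nan,
                "classifier_correct": np.nan}
    return {
        "id": name,
        "dice": table.dice.mean(),
        "hd95": table.hd95.mean(),
        "u_dice": table.u_dice.mean(),
        "classifier_correct": np.nan,
    }
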