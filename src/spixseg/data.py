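"""Multimodal MRI volumes, preprocessing, and 2-D slice datasets.

The pipeline consumes 4-channel axial slices (T1, post-contrast T1, T2,
T2-FLAIR) with a binary image-level label saying whether the slice contains
tumor.  This module turns 3-D multimodal volumes into such slices:

1. crop to the tight foreground (brain) bounding box,
2. clip non-zero intensities to their per-channel 1st/99th percentiles and
   min-max scale to [0, 1],
3. split into axial slices, discarding the first and last 30,
4. crop/pad each slice to a fixed square patch.

Array conventions: a volume is ``(4, H, W, D)`` with the axial depth on the
last axis; a slice is ``(4, H, W)``.  Reference masks are aligned binary
arrays used only for evaluation (and for deriving the image-level labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

N_CHANNELS = 4
MODALITY_ORDER = ("t1", "t1ce", "t2", "flair")


@dataclass
class MultimodalVolume:
    """Four co-registered 3-D modality grids plus an optional reference mask."""

    channels: np.ndarray  # (4, H, W, D)
    reference_mask: np.ndarray | None = None  # (H, W, D), binary
    patient_id: str = ""

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != N_CHANNELS:
            raise ValueError(
                f"expected channels of shape (4, H, W, D), got {self.channels.shape}"
            )
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("volume contains non-finite values")
        if self.reference_mask is not None:
            self.reference_mask = (np.asarray(self.reference_mask) > 0).astype(np.uint8)
            if self.reference_mask.shape != self.channels.shape[1:]:
                raise ValueError("reference_mask shape does not match channels")


@dataclass
class MultimodalSlice:
    """One 4-channel 2-D image with an image-level tumor label.

    ``label`` is 1 exactly when the slice's reference mask (if available at
    construction time) is non-empty.  The mask itself is carried only for
    evaluation; training never reads it.
    """

    pixels: np.ndarray  # (4, H, W), values in [0, 1]
    label: int
    reference_mask: np.ndarray | None = None  # (H, W)
    patient_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != N_CHANNELS:
            raise ValueError(f"expected pixels (4, H, W), got {self.pixels.shape}")
        self.label = int(self.label)
        if self.reference_mask is not None:
            self.reference_mask = (np.asarray(self.reference_mask) > 0).astype(np.uint8)
            if self.reference_mask.shape != self.pixels.shape[1:]:
                raise ValueError("reference_mask shape does not match pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1:]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def crop_to_foreground(volume: MultimodalVolume) -> MultimodalVolume:
    """Crop to the tightest box containing every voxel non-zero in any channel."""
    support = np.any(volume.channels != 0, axis=0)
    if not support.any():
        raise ValueError("no foreground: volume is zero in every channel")
    coords = np.nonzero(support)
    sl = tuple(slice(int(c.min()), int(c.max()) + 1) for c in coords)
    mask = volume.reference_mask[sl] if volume.reference_mask is not None else None
    return MultimodalVolume(
        channels=volume.channels[(slice(None),) + sl],
        reference_mask=mask,
        patient_id=volume.patient_id,
    )


def clip_and_normalize(
    volume: MultimodalVolume, lo_pct: float = 1.0, hi_pct: float = 99.0
) -> MultimodalVolume:
    """Clip non-zero intensities to per-channel percentiles, then min-max scale.

    Percentiles are computed over non-zero voxels only (zero background is
    ignored, and stays 0 after scaling whenever the channel minimum is 0).
    A channel with fewer than two distinct non-zero values degenerates to a
    binary foreground map (non-zeros -> 1) with a warning.
    """
    out = volume.channels.copy()
    for c in range(N_CHANNELS):
        ch = out[c]
        nz = ch[ch != 0]
        if np.unique(nz).size < 2:
            if nz.size:
                warnings.warn(
                    f"channel {c}: <2 distinct non-zero values; mapping non-zeros to 1"
                )
                ch[ch != 0] = 1.0
            else:
                warnings.warn(f"channel {c}: all-zero channel left unchanged")
            continue
        lo, hi = np.percentile(nz, [lo_pct, hi_pct])
        ch[ch != 0] = np.clip(ch[ch != 0], lo, hi)
        cmin, cmax = ch.min(), ch.max()
        if cmax == cmin:  # p1 == p99 collapsed the channel
            warnings.warn(f"channel {c}: constant after clipping; non-zeros set to 1")
            ch[ch != 0] = 1.0
            continue
        ch -= cmin
        ch /= (cmax - cmin)
    return MultimodalVolume(out, volume.reference_mask, volume.patient_id)


def volume_to_slices(
    volume: MultimodalVolume, drop_slices: int = 30
) -> list[MultimodalSlice]:
    """Split a volume into axial slices, discarding ``drop_slices`` at each end.

    Labels are derived from the reference mask: 1 iff the slice's mask is
    non-empty (0 everywhere when no mask is attached).
    """
    depth = volume.channels.shape[-1]
    if depth <= 2 * drop_slices:
        raise ValueError(
            f"axial depth {depth} too small: need more than {2 * drop_slices} slices"
        )
    slices = []
    for z in range(drop_slices, depth - drop_slices):
        mask = volume.reference_mask[..., z] if volume.reference_mask is not None else None
        label = int(mask.any()) if mask is not None else 0
        slices.append(
            MultimodalSlice(
                pixels=volume.channels[..., z],
                label=label,
                reference_mask=mask,
                patient_id=volume.patient_id,
                slice_index=z,
            )
        )
    return slices


def random_patch(
    image: MultimodalSlice, size: int = 128, rng_seed: int = 0
) -> MultimodalSlice:
    """Crop one ``size``×``size`` window (same window for all channels and mask).

    Deterministic for a fixed seed.  Inputs smaller than ``size`` are first
    zero-padded symmetrically, so geometry is preserved.
    """
    rng = np.random.default_rng(rng_seed)
    pixels, mask = image.pixels, image.reference_mask
    h, w = pixels.shape[1:]
    pad_h, pad_w = max(0, size - h), max(0, size - w)
    if pad_h or pad_w:
        pad = ((0, 0), (pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2))
        pixels = np.pad(pixels, pad)
        if mask is not None:
            mask = np.pad(mask, pad[1:])
        h, w = pixels.shape[1:]
    top = int(rng.integers(0, h - size + 1))
    left = int(rng.integers(0, w - size + 1))
    window = np.s_[top : top + size, left : left + size]
    return MultimodalSlice(
        pixels=pixels[(slice(None),) + window],
        label=image.label,
        reference_mask=mask[window] if mask is not None else None,
        patient_id=image.patient_id,
        slice_index=image.slice_index,
    )


def center_patch(image: MultimodalSlice, size: int = 128) -> MultimodalSlice:
    """Deterministic center crop used for validation/test slices."""
    pixels, mask = image.pixels, image.reference_mask
    h, w = pixels.shape[1:]
    pad_h, pad_w = max(0, size - h), max(0, size - w)
    if pad_h or pad_w:
        pad = ((0, 0), (pad_h // 2, pad_h - pad_h // 2), (pad_w // 2, pad_w - pad_w // 2))
        pixels = np.pad(pixels, pad)
        if mask is not None:
            mask = np.pad(mask, pad[1:])
        h, w = pixels.shape[1:]
    top, left = (h - size) // 2, (w - size) // 2
    window = np.s_[top : top + size, left : left + size]
    return MultimodalSlice(
        pixels=pixels[(slice(None),) + window],
        label=image.label,
        reference_mask=mask[window] if mask is not None else None,
        patient_id=image.patient_id,
        slice_index=image.slice_index,
    )


def split_cohorts(
    patients: list[str],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: int = 0,
) -> tuple[list[str], list[str], list[str]]:
    """Patient-level train/val/test split (never slice-level, so no leakage).

    Sizes are floor(train fraction) and round(val fraction); the remainder
    goes to test (369 patients at (0.8, 0.1, 0.1) gives 295/37/37).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    patients = list(patients)
    order = np.random.default_rng(rng_seed).permutation(len(patients))
    shuffled = [patients[i] for i in order]
    n_train = int(np.floor(fractions[0] * len(patients)))
    n_val = int(round(fractions[1] * len(patients)))
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )


# ---------------------------------------------------------------------------
# NIfTI I/O and dataset container
# ---------------------------------------------------------------------------

def read_nifti_volume(
    modality_paths: dict[str, str | Path],
    segmentation_path: str | Path | None = None,
    patient_id: str = "",
) -> MultimodalVolume:
    """Load one patient's modalities from NIfTI files.

    ``modality_paths`` maps modality keys (``t1``, ``t1ce``, ``t2``,
    ``flair``) to files; channels are stacked in that fixed order with the
    third array axis treated as axial depth.
    """
    import nibabel as nib

    arrays = []
    for key in MODALITY_ORDER:
        if key not in modality_paths:
            raise KeyError(f"missing modality {key!r}; need all of {MODALITY_ORDER}")
        arrays.append(np.asanyarray(nib.load(str(modality_paths[key])).dataobj))
    channels = np.stack(arrays, axis=0)
    mask = None
    if segmentation_path is not None:
        mask = np.asanyarray(nib.load(str(segmentation_path)).dataobj)
    return MultimodalVolume(channels, mask, patient_id)


def preprocess_volume(
    volume: MultimodalVolume,
    patch_size: int = 128,
    drop_slices: int = 30,
    rng_seed: int = 0,
    augment: bool = True,
) -> list[MultimodalSlice]:
    """Full preprocessing chain: crop, clip/normalize, slice, patch."""
    vol = clip_and_normalize(crop_to_foreground(volume))
    slices = volume_to_slices(vol, drop_slices=drop_slices)
    out = []
    for i, sl in enumerate(slices):
        if augment:
            out.append(random_patch(sl, patch_size, rng_seed=rng_seed + i))
        else:
            out.append(center_patch(sl, patch_size))
    return out


def save_slices(slices: list[MultimodalSlice], directory: str | Path,
                cohorts: dict[str, str] | None = None) -> Path:
    """Write a slice dataset: one ``slices.npz`` plus a CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pixels = np.stack([s.pixels for s in slices])
    labels = np.array([s.label for s in slices], dtype=np.uint8)
    has_mask = all(s.reference_mask is not None for s in slices)
    masks = (
        np.stack([s.reference_mask for s in slices]).astype(np.uint8)
        if has_mask
        else np.zeros((0,), dtype=np.uint8)
    )
    np.savez_compressed(directory / "slices.npz", pixels=pixels, labels=labels,
                        masks=masks)
    manifest = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in slices],
            "slice_index": [s.slice_index for s in slices],
            "label": labels,
            "cohort": [
                (cohorts or {}).get(s.patient_id, "unassigned") for s in slices
            ],
        }
    )
    manifest.to_csv(directory / "manifest.csv", index=False)
    return directory


def load_slices(directory: str | Path) -> list[MultimodalSlice]:
    directory = Path(directory)
    with np.load(directory / "slices.npz") as data:
        pixels, labels = data["pixels"], data["labels"]
        masks = data["masks"] if data["masks"].size else None
    manifest = pd.read_csv(directory / "manifest.csv")
    return [
        MultimodalSlice(
            pixels=pixels[i],
            label=int(labels[i]),
            reference_mask=masks[i] if masks is not None else None,
            patient_id=str(manifest.patient_id[i]),
            slice_index=int(manifest.slice_index[i]),
        )
        for i in range(len(labels))
    ]
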