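"""Training objective for the superpixel stage.

Two terms drive the joint training of generator and clusterer:

* ``spixel_loss`` — a soft-superpixel compactness/intensity loss.  With
  association-weighted mean intensity u_s and mean location l_s per
  superpixel, each pixel is reconstructed from its associations and the loss
  penalises the (unsquared) Euclidean reconstruction errors

      L_spixel = (1/N) Σ_k Σ_p ( ‖f(p) − Σ_s u_s q_s(p)‖₂
                                 + m·‖p − Σ_s l_s q_s(p)‖₂ ),

  so superpixels become homogeneous in intensity and spatially compact; the
  coefficient m (default 3/160, stated for raw pixel coordinates at the
  128×128 working scale) tunes superpixel size.
* ``seed_loss`` — the seeding term of the seed-expand-constrain family:
  negative log-likelihood of the soft clustering heatmap H+ on positive
  seeds and of 1−H+ on negative seeds, jointly normalised by the total seed
  count.

The combined objective is ``L = L_spixel + α·L_seed`` with α defaulting
to 50.  Everything here is differentiable end-to-end through both the
association maps Q and superpixel scores R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .rise import SeedMap

_MASS_EPS = 1e-12


@dataclass
class LossConfig:
    m: float = 3.0 / 160.0   # superpixel-size coefficient
    alpha: float = 50.0      # seed-loss weight
    eps: float = 1e-7        # log-stability floor

    def __post_init__(self):
        if self.m <= 0:
            raise ValueError("m must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass
class SuperpixelMoments:
    """Association-weighted first moments per superpixel (batched)."""

    u: Tensor     # (N, N_S, C) mean intensities
    l: Tensor     # (N, N_S, 2) mean (row, col) locations
    mass: Tensor  # (N, N_S) soft pixel counts; sums to H*W per image


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _pixel_coords(h: int, w: int, dtype) -> np.ndarray:
    """(H*W, 2) raw 0-based (row, col) coordinates, raster order."""
    yy, xx = np.mgrid[0:h, 0:w]
    return np.stack([yy.ravel(), xx.ravel()], axis=1).astype(dtype)


def superpixel_moments(pixels, q) -> SuperpixelMoments:
    """Soft per-superpixel mean intensity, mean location, and mass.

    ``pixels`` is (N, C, H, W) and ``q`` (N, N_S, H, W).  Zero-mass
    superpixels receive zero moments (their numerators vanish).
    """
    pixels, q = _coerce(pixels), _coerce(q)
    n, s, h, w = q.shape
    c = pixels.shape[1]
    qf = q.reshape(n, s, h * w)
    f = pixels.reshape(n, c, h * w)
    mass = qf.sum(axis=2)                                 # (N, S)
    sum_int = qf @ f.transpose(0, 2, 1)                   # (N, S, C)
    coords = Tensor(_pixel_coords(h, w, pixels.dtype))
    sum_pos = qf @ coords                                 # (N, S, 2)
    denom = (mass + _MASS_EPS).reshape(n, s, 1)
    return SuperpixelMoments(u=sum_int / denom, l=sum_pos / denom, mass=mass)


def spixel_loss_terms(pixels, q) -> tuple[Tensor, Tensor]:
    """Intensity and position reconstruction terms, each batch-averaged.

    Returned as (intensity_term, position_term) so the total is
    ``intensity + m * position``.
    """
    pixels, q = _coerce(pixels), _coerce(q)
    n, s, h, w = q.shape
    c = pixels.shape[1]
    moments = superpixel_moments(pixels, q)
    qf = q.reshape(n, s, h * w)
    f = pixels.reshape(n, c, h * w)
    recon_int = moments.u.transpose(0, 2, 1) @ qf          # (N, C, HW)
    res_int = f - recon_int
    int_norm = (res_int**2).sum(axis=1).sqrt_safe()        # (N, HW)
    coords = Tensor(_pixel_coords(h, w, pixels.dtype))     # (HW, 2)
    recon_pos = moments.l.transpose(0, 2, 1) @ qf          # (N, 2, HW)
    res_pos = coords.transpose(1, 0).reshape(1, 2, h * w) - recon_pos
    pos_norm = (res_pos**2).sum(axis=1).sqrt_safe()
    return int_norm.sum(axis=1).mean(), pos_norm.sum(axis=1).mean()


def spixel_loss(pixels, q, m: float = 3.0 / 160.0) -> Tensor:
    """Reconstruction form of the superpixel compactness/intensity loss."""
    intensity, position = spixel_loss_terms(pixels, q)
    return intensity + m * position


def _stack_seeds(seeds) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(seeds, SeedMap):
        seeds = [seeds]
    pos = np.stack([s.positive for s in seeds]).astype(np.float32)
    neg = np.stack([s.negative for s in seeds]).astype(np.float32)
    return pos, neg


def seed_loss(h_plus, seeds, eps: float = 1e-7) -> Tensor:
    """Seeding loss: −[Σ_{S+} log H+ + Σ_{S−} log(1−H+)] / (|S+|+|S−|).

    ``h_plus`` is (N, H, W) in [0, 1]; H− is taken as 1 − H+.  The
    denominator aggregates both seed classes jointly.  An image with no
    seeds at all contributes 0 (warned).
    """
    h_plus = _coerce(h_plus)
    if h_plus.ndim == 2:
        h_plus = h_plus.reshape(1, *h_plus.shape)
    pos, neg = _stack_seeds(seeds)
    counts = pos.sum(axis=(1, 2)) + neg.sum(axis=(1, 2))
    if np.any(counts == 0):
        warnings.warn("image(s) with no seeds contribute 0 to seed_loss")
    log_pos = (h_plus + eps).log() * Tensor(pos)
    log_neg = (1.0 - h_plus + eps).log() * Tensor(neg)
    per_image = -(log_pos.sum(axis=(1, 2)) + log_neg.sum(axis=(1, 2)))
    return (per_image / np.maximum(counts, 1.0)).mean()


def soft_cluster(q, r) -> Tensor:
    """Soft clustering heatmap H+ = Σ_s q_s · r_s (differentiable, batched)."""
    q, r = _coerce(q), _coerce(r)
    n, s = r.shape
    return (q * r.reshape(n, s, 1, 1)).sum(axis=1)


def combined_loss(pixels, q, r, seeds, config: LossConfig | None = None) -> Tensor:
    """Total objective L = L_spixel + α·L_seed, with H+ derived from (q, r)."""
    config = config or LossConfig()
    h_plus = soft_cluster(q, r)
    total = spixel_loss(pixels, q, config.m)
    if config.alpha > 0:
        total = total + config.alpha * seed_loss(h_plus, seeds, config.eps)
    return total
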