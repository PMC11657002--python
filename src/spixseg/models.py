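"""Stage 3 networks: superpixel generation and superpixel clustering.

The generator is a fully convolutional encoder–decoder (association-
implantation style trunk with skip connections) whose final 1×1 head emits
one channel per candidate superpixel at full resolution; a softmax across
that axis turns each pixel into a probability simplex over the N_S candidate
superpixels — the *global* soft association map Q.  The clustering network
is an image classifier (ResNet-18 at paper scale, a small residual net for
CPU work) that reads the image concatenated with Q and emits one score per
superpixel; a softmax yields R, the per-image simplex weighting each
superpixel's likelihood of containing tumor.

Both simplexes are the contract everything downstream relies on: the soft
clustering heatmap is H+ = Σ_s Q_s · R_s, so H+ is automatically in [0, 1].
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn.backbones import ResidualBlock


class SuperpixelGenerator(nn.Module):
    """Encoder–decoder FCN emitting global soft superpixel associations.

    ``forward`` requires H and W divisible by 4 (two 2× downsampling stages).
    Output: (N, n_superpixels, H, W), softmax-normalised over channel axis 1.
    """

    DOWN_FACTOR = 4

    def __init__(self, n_superpixels: int = 64, in_channels: int = 4,
                 base_channels: int = 16):
        super().__init__()
        self.n_superpixels = n_superpixels
        c = base_channels
        self.enc0 = nn.Sequential(
            nn.Conv2d(in_channels, c, 3, padding=1), nn.BatchNorm2d(c), nn.ReLU()
        )
        self.down1 = nn.Sequential(
            nn.Conv2d(c, 2 * c, 3, stride=2, padding=1), nn.BatchNorm2d(2 * c), nn.ReLU()
        )
        self.down2 = nn.Sequential(
            nn.Conv2d(2 * c, 4 * c, 3, stride=2, padding=1),
            nn.BatchNorm2d(4 * c), nn.ReLU(),
        )
        self.up1 = nn.Sequential(
            nn.Conv2d(4 * c, 2 * c, 3, padding=1), nn.BatchNorm2d(2 * c), nn.ReLU()
        )
        self.up0 = nn.Sequential(
            nn.Conv2d(4 * c, c, 3, padding=1), nn.BatchNorm2d(c), nn.ReLU()
        )
        self.fuse = nn.Sequential(
            nn.Conv2d(2 * c, c, 3, padding=1), nn.BatchNorm2d(c), nn.ReLU()
        )
        self.head = nn.Conv2d(c, n_superpixels, 1)

    def forward(self, x) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        h, w = x.shape[-2:]
        if h % self.DOWN_FACTOR or w % self.DOWN_FACTOR:
            raise ValueError(
                f"input size ({h}, {w}) must be divisible by the downsampling "
                f"factor {self.DOWN_FACTOR}"
            )
        e0 = self.enc0(x)                       # (N, c, H, W)
        e1 = self.down1(e0)                     # (N, 2c, H/2, W/2)
        e2 = self.down2(e1)                     # (N, 4c, H/4, W/4)
        d1 = self.up1(e2.upsample2x())          # (N, 2c, H/2, W/2)
        d0 = self.up0(nn.concat([d1, e1], axis=1).upsample2x())
        fused = self.fuse(nn.concat([d0, e0], axis=1))
        logits = self.head(fused)               # (N, N_S, H, W)
        return logits.softmax(axis=1)

    def associations(self, image) -> np.ndarray:
        """Association map Q for one slice, as a (N_S, H, W) numpy array."""
        from .classifier import _pixels

        self.eval()
        with nn.no_grad():
            q = self.forward(_pixels(image)[None])
        return q.data[0]


class SuperpixelClusterer(nn.Module):
    """Backbone classifier scoring each candidate superpixel for tumor content."""

    def __init__(self, n_superpixels: int = 64, in_channels: int = 4,
                 backbone: str = "resnet-small"):
        super().__init__()
        self.n_superpixels = n_superpixels
        self.backbone = nn.build_backbone(
            backbone, in_channels=in_channels + n_superpixels,
            num_outputs=n_superpixels,
        )

    def forward(self, x, q: nn.Tensor) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        if q.shape[1] != self.n_superpixels:
            raise ValueError(
                f"association map has {q.shape[1]} superpixel channels, "
                f"network head expects {self.n_superpixels}"
            )
        logits = self.backbone(nn.concat([x, q], axis=1))
        return logits.softmax(axis=1)

    def scores(self, image, q: np.ndarray) -> np.ndarray:
        """Superpixel scores R for one slice, as a length-N_S numpy array."""
        from .classifier import _pixels

        self.eval()
        with nn.no_grad():
            r = self.forward(_pixels(image)[None], nn.Tensor(q[None]))
        return r.data[0]


def count_effective_superpixels(q: np.ndarray) -> int:
    """Number of superpixels winning the argmax for at least one pixel.

    Soft association maps typically leave most of the N_S candidates with no
    assigned pixels; this counts the ones actually in use.  Argmax ties
    resolve to the lowest superpixel index.
    """
    q = np.asarray(q)
    if q.ndim != 3:
        raise ValueError("expected (N_S, H, W) association map")
    return int(np.unique(np.argmax(q, axis=0)).size)


def save_models(generator: SuperpixelGenerator, clusterer: SuperpixelClusterer,
                path) -> None:
    import json

    gen_state = {f"gen::{k}": v for k, v in generator.state_dict().items()}
    clu_state = {f"clu::{k}": v for k, v in clusterer.state_dict().items()}
    meta = json.dumps({"n_superpixels": generator.n_superpixels})
    np.savez_compressed(path, __meta__=meta, **gen_state, **clu_state)


def load_models(path, base_channels: int = 16, backbone: str = "resnet-small",
                in_channels: int = 4) -> tuple[SuperpixelGenerator, SuperpixelClusterer]:
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        gen_state = {k[5:]: data[k] for k in data.files if k.startswith("gen::")}
        clu_state = {k[5:]: data[k] for k in data.files if k.startswith("clu::")}
    generator = SuperpixelGenerator(meta["n_superpixels"], in_channels, base_channels)
    clusterer = SuperpixelClusterer(meta["n_superpixels"], in_channels, backbone)
    generator.load_state_dict(gen_state)
    clusterer.load_state_dict(clu_state)
    generator.eval()
    clusterer.eval()
    return generator, clusterer
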