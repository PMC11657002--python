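"""Image-classification backbones built from the layer toolkit.

Every backbone maps a (N, C, H, W) batch to (N, num_outputs) logits through
the same contract, so the classifier and superpixel-clustering stages are
architecture-agnostic: any entry registered here (or any user Module with the
same signature) trains through identical code paths.

``vgg16-bn`` and ``resnet18`` follow the standard 13-conv VGG-16 (batch-norm
variant) and 8-block ResNet-18 layouts; the ``*-small`` entries are narrow
desk-scale counterparts used for CPU runs and tests.
"""

from __future__ import annotations

from .layers import (
    AvgPool2x,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2x,
    Module,
    ReLU,
    Sequential,
)
from .tensor import Tensor

_VGG16_CFG = [64, 64, "M", 128, 128, "M", 256, 256, 256, "M", 512, 512, 512, "M",
              512, 512, 512, "M"]
_VGG_SMALL_CFG = [8, "M", 16, "M", 32, "M"]


def _vgg(cfg: list, in_channels: int, num_outputs: int) -> Module:
    layers: list[Module] = []
    ch = in_channels
    for item in cfg:
        if item == "M":
            layers.append(MaxPool2x())
        else:
            layers += [Conv2d(ch, item, 3, padding=1), BatchNorm2d(item), ReLU()]
            ch = item
    layers += [GlobalAvgPool(), Linear(ch, num_outputs)]
    return Sequential(*layers)


class ResidualBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = BatchNorm2d(out_ch)
        self.shortcut = None
        if stride != 1 or in_ch != out_ch:
            self.shortcut = Sequential(
                Conv2d(in_ch, out_ch, 1, stride=stride, bias=False), BatchNorm2d(out_ch)
            )

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        skip = x if self.shortcut is None else self.shortcut(x)
        return (out + skip).relu()


def _resnet(stages: list[tuple[int, int]], stem_ch: int, in_channels: int,
            num_outputs: int) -> Module:
    layers: list[Module] = [Conv2d(in_channels, stem_ch, 3, padding=1, bias=False),
                            BatchNorm2d(stem_ch), ReLU()]
    ch = stem_ch
    for i, (out_ch, blocks) in enumerate(stages):
        for j in range(blocks):
            stride = 2 if (j == 0 and i > 0) else 1
            layers.append(ResidualBlock(ch, out_ch, stride))
            ch = out_ch
    layers += [GlobalAvgPool(), Linear(ch, num_outputs)]
    return Sequential(*layers)


_REGISTRY = {
    "vgg16-bn": lambda c, o: _vgg(_VGG16_CFG, c, o),
    "vgg-small": lambda c, o: _vgg(_VGG_SMALL_CFG, c, o),
    "resnet18": lambda c, o: _resnet([(64, 2), (128, 2), (256, 2), (512, 2)], 64, c, o),
    "resnet-small": lambda c, o: _resnet([(16, 1), (32, 1)], 16, c, o),
}


def build_backbone(name: str, in_channels: int, num_outputs: int = 1) -> Module:
    """Instantiate a registered backbone producing ``num_outputs`` logits."""
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown backbone {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return factory(in_channels, num_outputs)


def available_backbones() -> list[str]:
    return sorted(_REGISTRY)
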