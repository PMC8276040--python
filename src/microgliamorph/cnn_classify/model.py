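"""VGG-16-style model construction: full-scale and reduced CPU presets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import BatchNorm, Conv3x3, Dense, Dropout, Flatten, MaxPool2, ReLU, Sequential

#: VGG-16 convolutional plan: 13 conv layers in 5 max-pooled blocks.
VGG16_PLAN = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))
VGG16_FC = (4096, 4096)
N_CLASSES = 4


@dataclass
class ModelSpec:
    preset: str = "full_vgg16"  # or "reduced"
    input_side: int = 128
    width_factor: float = 1.0
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        if self.preset not in ("full_vgg16", "reduced"):
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.width_factor <= 0:
            raise ValueError("width_factor must be > 0")
        if self.input_side % 2 ** len(VGG16_PLAN) != 0:
            raise ValueError("input_side must be divisible by 32 (five 2x2 pools)")


def reduced_spec(input_side: int = 64, width_factor: float = 1 / 8) -> ModelSpec:
    """Desk-scale preset: same topology, narrower and on smaller inputs."""
    return ModelSpec(preset="reduced", input_side=input_side, width_factor=width_factor)


def build_model(spec: ModelSpec, dropout: float = 0.5, seed: int = 0) -> Sequential:
    """Build the network: 13 conv + 5 max-pool + 2 FC + n-class softmax head.

    Layer pattern is conv -> ReLU -> BatchNorm per convolution (normalization
    after each activation); dropout constrains the fully connected layers.
    The returned network outputs logits; pair with ``_nn.softmax`` /
    ``softmax_cross_entropy``.
    """
    rng = np.random.default_rng(seed)
    wf = spec.width_factor if spec.preset == "reduced" else 1.0
    scale_c = lambda c: max(4, int(round(c * wf)))
    layers = []
    in_ch = 1
    for block in VGG16_PLAN:
        for c in block:
            ch = scale_c(c)
            layers += [Conv3x3(in_ch, ch, rng), ReLU(), BatchNorm(ch)]
            in_ch = ch
        layers.append(MaxPool2())
    layers.append(Flatten())
    feat = (spec.input_side // 2 ** len(VGG16_PLAN)) ** 2 * in_ch
    for width in VGG16_FC:
        fc = max(16, int(round(width * wf)))
        layers += [Dense(feat, fc, rng), ReLU(), BatchNorm(fc), Dropout(dropout, rng)]
        feat = fc
    layers.append(Dense(feat, spec.n_classes, rng))
    return Sequential(layers)


def count_conv_layers(network: Sequential) -> int:
    return sum(isinstance(layer, Conv3x3) for layer in network.layers)


def count_pool_layers(network: Sequential) -> int:
    return sum(isinstance(layer, MaxPool2) for layer in network.layers)


def count_fc_layers(network: Sequential) -> int:
    """Fully connected layers excluding the softmax head."""
    return sum(isinstance(layer, Dense) for layer in network.layers) - 1
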