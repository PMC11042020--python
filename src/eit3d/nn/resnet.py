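"""Bottleneck residual regression network: 45 x 48 feature map -> N outputs.

The stem is a 7x7/stride-2/pad-3 convolution to 64 channels (45x48 input ->
64 x 23 x 24), followed by 3x3/stride-2/pad-1 max pooling and four stages of
bottleneck blocks. Each stage entry uses a projection-shortcut bottleneck
(downsampling variant); the remaining blocks use identity shortcuts. Global
average pooling yields a vector of length ``4 * last_width`` (2,048 for the
default (64, 128, 256, 512) widths) and a single fully connected layer maps
it to the per-element conductivity vector.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Layer,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
)

EXPANSION = 4


class Bottleneck(Layer):
    """1x1 -> 3x3 -> 1x1 residual block with identity or projection shortcut."""

    def __init__(self, c_in, width, stride, rng):
        c_out = width * EXPANSION
        self.main = Sequential(
            Conv2d(c_in, width, 1, rng=rng), BatchNorm2d(width), ReLU(),
            Conv2d(width, width, 3, stride=stride, pad=1, rng=rng), BatchNorm2d(width), ReLU(),
            Conv2d(width, c_out, 1, rng=rng), BatchNorm2d(c_out),
        )
        if stride != 1 or c_in != c_out:
            self.shortcut = Sequential(Conv2d(c_in, c_out, 1, stride=stride, rng=rng),
                                       BatchNorm2d(c_out))
        else:
            self.shortcut = None
        self.relu = ReLU()

    def params(self):
        p = self.main.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def forward(self, x, train=True):
        out = self.main.forward(x, train)
        res = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu.forward(out + res, train)

    def backward(self, grad):
        grad = self.relu.backward(grad)
        dres = grad if self.shortcut is None else self.shortcut.backward(grad)
        dx = self.main.backward(grad)
        return dx + dres


class BottleneckRegressor(Layer):
    def __init__(
        self,
        output_dim: int,
        stage_depths=(3, 4, 6, 3),
        stage_widths=(64, 128, 256, 512),
        stem_channels: int = 64,
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        self.stem = Sequential(
            Conv2d(1, stem_channels, 7, stride=2, pad=3, rng=rng),
            BatchNorm2d(stem_channels),
            ReLU(),
            MaxPool2d(3, 2, 1),
        )
        blocks: list[Layer] = []
        c_in = stem_channels
        for s, (depth, width) in enumerate(zip(stage_depths, stage_widths)):
            for b in range(depth):
                stride = 2 if (b == 0 and s > 0) else 1
                blocks.append(Bottleneck(c_in, width, stride, rng))
                c_in = width * EXPANSION
        self.blocks = Sequential(*blocks)
        self.pool = GlobalAvgPool()
        self.pooled_dim = stage_widths[-1] * EXPANSION
        self.fc = Linear(self.pooled_dim, output_dim, rng=rng)
        self.output_dim = output_dim

    def params(self):
        return self.stem.params() + self.blocks.params() + self.fc.params()

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        h = self.stem.forward(x, train)
        h = self.blocks.forward(h, train)
        v = self.pool.forward(h, train)
        return self.fc.forward(v, train)

    def backward(self, grad):
        g = self.fc.backward(grad.astype(np.float32))
        g = self.pool.backward(g)
        g = self.blocks.backward(g)
        return self.stem.backward(g)

    # -- introspection used by shape tests and docs -----------------------
    def shape_chain(self, in_hw=(45, 48)):
        """Intermediate activation shapes for a single input map."""
        x = np.zeros((1, 1, *in_hw), dtype=np.float32)
        chain = []
        h = self.stem.layers[0].forward(x, train=False)
        chain.append(("stem_conv", h.shape[1:]))
        for l in self.stem.layers[1:]:
            h = l.forward(h, train=False)
        chain.append(("stem_pool", h.shape[1:]))
        for i, blk in enumerate(self.blocks.layers):
            h = blk.forward(h, train=False)
        chain.append(("last_block", h.shape[1:]))
        v = self.pool.forward(h, train=False)
        chain.append(("pooled", v.shape[1:]))
        chain.append(("output", (self.output_dim,)))
        return chain

    def state_dict(self) -> dict:
        state = {}
        for i, (p, _) in enumerate(self.params()):
            state[f"p{i}"] = p.copy()
        bn = [l for l in _iter_layers(self) if isinstance(l, BatchNorm2d)]
        for i, l in enumerate(bn):
            state[f"bn{i}_mean"] = l.running_mean.copy()
            state[f"bn{i}_var"] = l.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, (p, _) in enumerate(self.params()):
            p[...] = state[f"p{i}"]
        bn = [l for l in _iter_layers(self) if isinstance(l, BatchNorm2d)]
        for i, l in enumerate(bn):
            l.running_mean[...] = state[f"bn{i}_mean"]
            l.running_var[...] = state[f"bn{i}_var"]


def _iter_layers(root):
    stack = [root]
    while stack:
        l = stack.pop(0)
        yield l
        if isinstance(l, Sequential):
            stack = l.layers + stack
        elif isinstance(l, Bottleneck):
            sub = [l.main] + ([l.shortcut] if l.shortcut is not None else [])
            stack = sub + stack
        elif isinstance(l, BottleneckRegressor):
            stack = [l.stem, l.blocks] + stack
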