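"""Symmetric encoder-decoder segmentation network with skip connections.

Each encoder stage is two 3x3 conv+ReLU blocks followed by 2x2 max-pooling;
the decoder mirrors it with nearest-neighbour upsampling and concatenation
of the matching encoder feature map, so fine spatial detail survives the
bottleneck.  A final 1x1 convolution and per-pixel softmax produce class
probabilities at input resolution.  Channel widths start at ``base_filters``
and double per stage.
"""

from __future__ import annotations

import numpy as np

from ..config import UNetSpec
from .layers import BatchNorm2D, Conv2D, MaxPool2x2, ReLU, Upsample2x, softmax_channels, softmax_backward


class _ConvBlock:
    """conv3x3 -> batchnorm -> ReLU, twice."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        self.c1 = Conv2D(rng, in_ch, out_ch)
        self.b1 = BatchNorm2D(out_ch)
        self.r1 = ReLU()
        self.c2 = Conv2D(rng, out_ch, out_ch)
        self.b2 = BatchNorm2D(out_ch)
        self.r2 = ReLU()

    def forward(self, x):
        x = self.r1.forward(self.b1.forward(self.c1.forward(x)))
        return self.r2.forward(self.b2.forward(self.c2.forward(x)))

    def backward(self, dy):
        dy = self.c2.backward(self.b2.backward(self.r2.backward(dy)))
        return self.c1.backward(self.b1.backward(self.r1.backward(dy)))

    @property
    def convs(self):
        return [self.c1, self.c2]

    @property
    def norms(self):
        return [self.b1, self.b2]


class UNet:
    """NumPy U-net: forward to per-pixel class probabilities, full backprop."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.base_filters
        self.enc: list[_ConvBlock] = []
        self.pools: list[MaxPool2x2] = []
        in_ch = spec.in_channels
        widths = [f * 2**d for d in range(spec.depth)]
        for w in widths:
            self.enc.append(_ConvBlock(rng, in_ch, w))
            self.pools.append(MaxPool2x2())
            in_ch = w
        self.bottleneck = _ConvBlock(rng, in_ch, f * 2**spec.depth)
        self.ups: list[Upsample2x] = []
        self.dec: list[_ConvBlock] = []
        up_ch = f * 2**spec.depth
        for w in reversed(widths):
            self.ups.append(Upsample2x())
            self.dec.append(_ConvBlock(rng, up_ch + w, w))
            up_ch = w
        self.head = Conv2D(rng, up_ch, spec.n_classes, kernel=1)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, in_channels, H, W) -> (N, n_classes, H, W) probabilities.

        H and W must be divisible by 2**depth.
        """
        n, c, h, w = x.shape
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channels, got {c}")
        stride = 2**self.spec.depth
        if h % stride or w % stride:
            raise ValueError(f"spatial dims must be divisible by {stride}")
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottleneck.forward(x)
        self._skip_ch = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x)
            self._skip_ch.append((x.shape[1], skip.shape[1]))
            x = np.concatenate([x, skip], axis=1)
            x = block.forward(x)
        logits = self.head.forward(x)
        self._probs = softmax_channels(logits)
        return self._probs

    def backward(self, dprobs: np.ndarray) -> None:
        """Backprop dL/dprobs through the network, filling conv gradients."""
        dy = softmax_backward(self._probs, dprobs)
        dy = self.head.backward(dy)
        dskips = []
        for up, block, (up_ch, _) in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_ch)
        ):
            dcat = block.backward(dy)
            dskips.append(dcat[:, up_ch:])
            dy = up.backward(dcat[:, :up_ch])
        dy = self.bottleneck.backward(dy)
        # dskips was collected shallowest-decoder-first, i.e. enc[0]'s skip
        # first; the encoder unwinds deepest-first, so pair with reversed(dskips)
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            dy = block.backward(pool.backward(dy) + dskip)

    # -- parameters ----------------------------------------------------------

    def _blocks(self):
        return self.enc + [self.bottleneck] + self.dec

    def conv_layers(self) -> list[Conv2D]:
        layers = []
        for block in self._blocks():
            layers += block.convs
        layers.append(self.head)
        return layers

    def norm_layers(self) -> list[BatchNorm2D]:
        layers = []
        for block in self._blocks():
            layers += block.norms
        return layers

    def set_training(self, training: bool) -> None:
        """Toggle batch-norm between batch statistics and running statistics."""
        for bn in self.norm_layers():
            bn.training = training

    def sgdm_step(self, lr: float, momentum: float, l2: float) -> None:
        """SGDM update, v <- m v - lr (g + l2 w); the L2 penalty applies to
        convolution weights only (not biases or normalisation parameters)."""
        for layer in self.conv_layers():
            (w, gw, vw), (b, gb, vb) = layer.params
            vw *= momentum
            vw -= lr * (gw + l2 * w)
            w += vw
            vb *= momentum
            vb -= lr * gb
            b += vb
        for bn in self.norm_layers():
            for w, g, v in bn.params:
                v *= momentum
                v -= lr * g
                w += v

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.conv_layers():
            out += [layer.w.copy(), layer.b.copy()]
        for bn in self.norm_layers():
            out += [bn.gamma.copy(), bn.beta.copy(), bn.running_mean.copy(), bn.running_var.copy()]
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        convs = self.conv_layers()
        norms = self.norm_layers()
        if len(weights) != 2 * len(convs) + 4 * len(norms):
            raise ValueError("weight list does not match architecture")
        k = 0
        for layer in convs:
            layer.w[...] = weights[k]
            layer.b[...] = weights[k + 1]
            k += 2
        for bn in norms:
            bn.gamma[...] = weights[k]
            bn.beta[...] = weights[k + 1]
            bn.running_mean[...] = weights[k + 2]
            bn.running_var[...] = weights[k + 3]
            k += 4
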