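"""Encoder-decoder networks built on the engine layers.

``UNet`` is a classic symmetric encoder-decoder with skip connections; when
given a ``basis`` its encoder convolutions become basis-constrained (only
linear-combination coefficients are trained).  ``StackedUNet`` chains two
U-nets: the second is fed the channel-concatenation of the original input
and the first network's output.
"""

from __future__ import annotations

import numpy as np

from .engine import (
    Adam, Conv2d, ConstrainedConv2d, HardSigmoid, Layer, MaxPool2, ReLU,
    Upsample2,
)

__all__ = ["UNet", "StackedUNet"]


def _make_conv(cin: int, cout: int, k: int, basis: np.ndarray | None,
               rng: np.random.Generator) -> Layer:
    if basis is not None:
        return ConstrainedConv2d(cin, cout, basis, rng=rng)
    return Conv2d(cin, cout, k, rng=rng)


class UNet:
    """Symmetric encoder-decoder with skip connections.

    Parameters
    ----------
    in_channels : input channel count.
    depth : number of pooling steps; input spatial size must be divisible
        by ``2**depth``.
    base_channels : channels at the finest level; doubled per level.
    kernel_size : spatial size of the free convolutions.
    basis : optional (n_basis, k, k) fixed kernel family; when given, every
        encoder convolution is constrained to linear combinations of it.
    """

    def __init__(self, in_channels: int = 1, depth: int = 3,
                 base_channels: int = 8, kernel_size: int = 3,
                 basis: np.ndarray | None = None,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.depth = depth
        self.base_channels = base_channels
        ch = [base_channels * 2 ** i for i in range(depth + 1)]

        self.enc_blocks: list[list[Layer]] = []
        cin = in_channels
        for i in range(depth):
            block = [
                _make_conv(cin, ch[i], kernel_size, basis, rng), ReLU(),
                _make_conv(ch[i], ch[i], kernel_size, basis, rng), ReLU(),
            ]
            self.enc_blocks.append(block)
            cin = ch[i]
        self.pools = [MaxPool2() for _ in range(depth)]

        self.bottleneck: list[Layer] = [
            Conv2d(ch[depth - 1], ch[depth], kernel_size, rng=rng), ReLU(),
            Conv2d(ch[depth], ch[depth], kernel_size, rng=rng), ReLU(),
        ]

        self.ups = [Upsample2() for _ in range(depth)]
        self.dec_blocks: list[list[Layer]] = []
        for i in reversed(range(depth)):
            block = [
                Conv2d(ch[i + 1], ch[i], kernel_size, rng=rng), ReLU(),
                # after concat with the skip the channel count doubles
                Conv2d(2 * ch[i], ch[i], kernel_size, rng=rng), ReLU(),
                Conv2d(ch[i], ch[i], kernel_size, rng=rng), ReLU(),
            ]
            self.dec_blocks.append(block)
        self.head: list[Layer] = [Conv2d(ch[0], 1, 1, rng=rng), HardSigmoid()]

    # -- plumbing ---------------------------------------------------------

    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for b in self.enc_blocks:
            out.extend(b)
        out.extend(self.pools)
        out.extend(self.bottleneck)
        out.extend(self.ups)
        for b in self.dec_blocks:
            out.extend(b)
        out.extend(self.head)
        return out

    def parameter_count(self) -> int:
        return sum(p.size for l in self.layers() for p in l.params.values())

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % (2 ** self.depth) or x.shape[3] % (2 ** self.depth):
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by 2^depth={2 ** self.depth}"
            )
        skips = []
        h = x
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                h = layer.forward(h)
            skips.append(h)
            h = pool.forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h)
            h = block[0].forward(h)
            h = block[1].forward(h)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            for layer in block[2:]:
                h = layer.forward(h)
        for layer in self.head:
            h = layer.forward(h)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h = dout
        for layer in reversed(self.head):
            h = layer.backward(h)
        dskips = []
        for up, block, c_skip in zip(reversed(self.ups), reversed(self.dec_blocks),
                                     reversed(self._skip_channels)):
            for layer in reversed(block[2:]):
                h = layer.backward(h)
            dskip, h = h[:, :c_skip], h[:, c_skip:]
            dskips.append(dskip)
            h = block[1].backward(h)
            h = block[0].backward(h)
            h = up.backward(h)
        for layer in reversed(self.bottleneck):
            h = layer.backward(h)
        for block, pool, dskip in zip(reversed(self.enc_blocks),
                                      reversed(self.pools), reversed(dskips)):
            h = pool.backward(h)
            h = h + dskip
            for layer in reversed(block):
                h = layer.backward(h)
        return h

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class StackedUNet:
    """Two chained U-nets; the second sees input ++ first-stage output."""

    def __init__(self, unet1: UNet, unet2: UNet) -> None:
        if unet2.in_channels != unet1.in_channels + 1:
            raise ValueError(
                "second U-net must accept one extra channel "
                f"({unet1.in_channels}+1 != {unet2.in_channels})"
            )
        self.unet1 = unet1
        self.unet2 = unet2

    def layers(self) -> list[Layer]:
        return self.unet1.layers() + self.unet2.layers()

    def parameter_count(self) -> int:
        return self.unet1.parameter_count() + self.unet2.parameter_count()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y1 = self.unet1.forward(x)
        h = np.concatenate([x, self._y1], axis=1)
        return self.unet2.forward(h)

    @property
    def stage1_output(self) -> np.ndarray:
        """First U-net's output from the most recent forward pass."""
        return self._y1

    def backward(self, dout: np.ndarray,
                 dstage1: np.ndarray | None = None) -> np.ndarray:
        """Backpropagate the loss gradient.

        ``dstage1`` optionally adds a gradient applied directly to the
        first U-net's output (deep supervision); without it the first
        stage is trained only through the second stage's input channel.
        """
        dh = self.unet2.backward(dout)
        dx_direct, dy1 = dh[:, :-1], dh[:, -1:]
        if dstage1 is not None:
            dy1 = dy1 + dstage1
        dx = self.unet1.backward(dy1)
        return dx + dx_direct

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.layers(), lr=lr)
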