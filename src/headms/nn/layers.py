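"""Parameterized layers and the module container used by the U-Net builders."""

from __future__ import annotations

import numpy as np

from . import engine as E
from .engine import Param, Tensor


class Module:
    """Base container; collects parameters/buffers recursively by attribute scan."""

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self):
        """Trainable parameters (optimized by Adam)."""
        for v in self.__dict__.values():
            if isinstance(v, Param):
                yield v
        for child in self._children():
            yield from child.parameters()

    def buffers(self):
        """Non-trainable stored arrays (normalization running statistics)."""
        for v in self.__dict__.values():
            if isinstance(v, np.ndarray):
                yield v
        for child in self._children():
            yield from child.buffers()

    def n_stored_parameters(self) -> int:
        """Total stored values: trainable parameters plus buffers."""
        return sum(p.data.size for p in self.parameters()) + sum(
            b.size for b in self.buffers()
        )

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_arrays(self):
        """All stored arrays in deterministic order, for save/restore."""
        return [p.data for p in self.parameters()] + list(self.buffers())


class Conv2d(Module):
    """Same-padded k x k convolution with bias; weight kept in im2col layout."""

    def __init__(self, cin, cout, k=3, rng=None):
        self.k = k
        fan_in = k * k * cin
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU networks
        rng = rng or np.random.default_rng()
        self.w = Param(rng.normal(0.0, std, size=(fan_in, cout)))
        self.b = Param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        if self.k == 1:
            return E.conv1x1(x, self.w, self.b)
        return E.conv2d(x, self.w, self.b, self.k)


class Conv1x1Strided(Module):
    """Pointwise convolution with spatial stride (attention-gate resampler)."""

    def __init__(self, cin, cout, stride=2, rng=None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / cin)
        self.stride = stride
        self.w = Param(rng.normal(0.0, std, size=(cin, cout)))
        self.b = Param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return E.conv1x1(x, self.w, self.b, stride=self.stride)


class ConvTranspose2x(Module):
    """3x3 stride-2 transposed convolution (spatial doubling), bias, no norm."""

    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng()
        fan_in = 9 * cin
        std = np.sqrt(2.0 / fan_in)
        self.w = Param(rng.normal(0.0, std, size=(fan_in, cout)))
        self.b = Param(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return E.conv_transpose2x(x, self.w, self.b)


class BatchNorm2d(Module):
    """Channel-wise normalization; stores 4 values per channel
    (affine scale/shift plus running mean/variance)."""

    def __init__(self, c):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return E.batchnorm(
            x, self.gamma, self.beta, self.running_mean, self.running_var, training
        )


class ConvBNReLU(Module):
    def __init__(self, cin, cout, k=3, rng=None):
        self.conv = Conv2d(cin, cout, k=k, rng=rng)
        self.bn = BatchNorm2d(cout)

    def __call__(self, x, training):
        return E.relu(self.bn(self.conv(x), training))


class DoubleConv(Module):
    """[3x3 conv -> norm -> ReLU] x 2, the canonical U-Net block."""

    def __init__(self, cin, cout, rng=None):
        self.c1 = ConvBNReLU(cin, cout, rng=rng)
        self.c2 = ConvBNReLU(cout, cout, rng=rng)

    def __call__(self, x, training):
        return self.c2(self.c1(x, training), training)
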