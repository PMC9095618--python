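"""Network layers and residual blocks built on the autodiff engine.

Residual blocks follow the pre-activation layout: two stacks of
BatchNorm -> ReLU -> (transposed) convolution, with the first convolution
strided (2, 2) in the resampling blocks and a matching 1x1 projection on
the shortcut.  A down/upsampling block is two such residual blocks, the
first one resampling.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
           "ResidualBlock", "SamplingBlock"]


class Module:
    """Minimal parameter container."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of parameters and buffers (for checkpoints)."""
        out: dict[str, np.ndarray] = {}
        for name, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[name] = v.data
            elif isinstance(v, np.ndarray):
                out[name] = v
            elif isinstance(v, Module):
                for k, arr in v.state_arrays().items():
                    out[f"{name}.{k}"] = arr
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        for k, arr in item.state_arrays().items():
                            out[f"{name}.{i}.{k}"] = arr
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(state[key]).astype(v.dtype).reshape(v.shape)
            elif isinstance(v, np.ndarray):
                setattr(self, name, np.asarray(state[key]).astype(v.dtype).reshape(v.shape))
            elif isinstance(v, Module):
                v.load_state_arrays(state, prefix=f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(state, prefix=f"{key}.{i}.")


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)      # He initialization for ReLU stacks
        self.weight = Tensor((rng.standard_normal((cout, cin, k, k)) * scale)
                             .astype(dtype), requires_grad=True)
        self.stride = stride
        self.padding = (k - 1) // 2 if padding is None else padding

    def forward(self, x: Tensor, training: bool = True) -> Tensor:
        return T.conv2d(x, self.weight, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor((rng.standard_normal((cin, cout, k, k)) * scale)
                             .astype(dtype), requires_grad=True)
        self.stride = stride
        self.padding = (k - 1) // 2
        self.output_padding = stride - 1

    def forward(self, x: Tensor, training: bool = True) -> Tensor:
        return T.conv_transpose2d(x, self.weight, stride=self.stride,
                                  padding=self.padding,
                                  output_padding=self.output_padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor, training: bool = True) -> Tensor:
        if training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu.astype(self.running_mean.dtype)
                                                  - self.running_mean)
            self.running_var += self.momentum * (var.astype(self.running_var.dtype)
                                                 - self.running_var)
            xhat = T.batchnorm2d(x, self.eps)
            return T.scale_shift_channels(xhat, self.gamma, self.beta)
        # eval mode: fold normalization and affine into one pass with the
        # frozen running statistics (parameter gradients are not tracked here)
        inv = 1.0 / np.sqrt(self.running_var.astype(x.dtype) + self.eps)
        a = (self.gamma.data * inv).astype(x.dtype)
        b = (self.beta.data - self.gamma.data * self.running_mean * inv).astype(x.dtype)
        return T.affine_channels(x, a, b)


class ResidualBlock(Module):
    """Pre-activation residual block: (BN-ReLU-conv) x 2 + shortcut.

    ``mode`` selects the first convolution: "same" (stride 1), "down"
    (stride-2 convolution) or "up" (stride-2 transposed convolution); the
    shortcut uses a matching strided 1x1 (transposed) convolution whenever
    the shape changes.
    """

    def __init__(self, cin: int, cout: int, mode: str = "same",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        self.bn1 = BatchNorm2d(cin, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        if mode == "down":
            self.conv1 = Conv2d(cin, cout, stride=2, rng=rng, dtype=dtype)
            self.shortcut = Conv2d(cin, cout, k=1, stride=2, padding=0,
                                   rng=rng, dtype=dtype)
        elif mode == "up":
            self.conv1 = ConvTranspose2d(cin, cout, stride=2, rng=rng, dtype=dtype)
            self.shortcut = ConvTranspose2d(cin, cout, k=1, stride=2,
                                            rng=rng, dtype=dtype)
            self.shortcut.padding = 0
            self.shortcut.output_padding = 1
        elif mode == "same":
            self.conv1 = Conv2d(cin, cout, stride=1, rng=rng, dtype=dtype)
            self.shortcut = (None if cin == cout
                             else Conv2d(cin, cout, k=1, padding=0, rng=rng,
                                         dtype=dtype))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        self.conv2 = Conv2d(cout, cout, stride=1, rng=rng, dtype=dtype)

    def forward(self, x: Tensor, training: bool = True) -> Tensor:
        h = T.relu(self.bn1.forward(x, training))
        h = self.conv1.forward(h, training)
        h = T.relu(self.bn2.forward(h, training))
        h = self.conv2.forward(h, training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training)
        return T.add(h, s)


class SamplingBlock(Module):
    """A down- or upsampling block: a resampling residual block followed by a
    stride-1 residual block."""

    def __init__(self, cin: int, cout: int, mode: str,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        self.res1 = ResidualBlock(cin, cout, mode=mode, rng=rng, dtype=dtype)
        self.res2 = ResidualBlock(cout, cout, mode="same", rng=rng, dtype=dtype)

    def forward(self, x: Tensor, training: bool = True) -> Tensor:
        return self.res2.forward(self.res1.forward(x, training), training)
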