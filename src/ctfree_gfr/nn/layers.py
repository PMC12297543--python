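"""Network building blocks: convolution blocks, attention gates, 3D U-Net.

The U-Net follows the standard encoder-decoder layout: channel width doubles
at each of ``depth`` poolings starting from ``initial_neurons``, decoder
levels upsample with nearest-neighbor interpolation and concatenate the
encoder skip tensor.  Blocks are two conv3-instance_norm-ReLU stages, with an
identity shortcut in the residual variant.  The attention variant gates each
skip connection with an additive attention coefficient map driven by the
coarser decoder signal, optionally augmented with a spatial-gradient (edge)
feature of the skip tensor so boundaries are emphasized.
"""

from __future__ import annotations

import numpy as np

from .autograd import (Tensor, avg_pool3d, concat, conv3d, edge_magnitude,
                       instance_norm, softmax_channels, upsample_nearest3d)

__all__ = ["Parameter", "Module", "Conv3d", "InstanceNorm3d", "ConvBlock",
           "AttentionGate", "UNet3D"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter collection and flat state dicts."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        fan_in = c_in * kernel**3
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    def __init__(self, channels: int):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))

    def forward(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta)


class ConvBlock(Module):
    """conv3-IN-ReLU x2; the residual variant adds an identity shortcut
    (1x1x1 projection when the channel count changes)."""

    def __init__(self, c_in: int, c_out: int, residual: bool,
                 rng: np.random.Generator, norm: str = "instance"):
        if norm != "instance":
            raise NotImplementedError("only instance normalization is implemented")
        self.residual = residual
        self.conv1 = Conv3d(c_in, c_out, 3, rng)
        self.norm1 = InstanceNorm3d(c_out)
        self.conv2 = Conv3d(c_out, c_out, 3, rng)
        self.norm2 = InstanceNorm3d(c_out)
        self.proj = Conv3d(c_in, c_out, 1, rng) if residual and c_in != c_out else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        if self.residual:
            shortcut = self.proj(x) if self.proj is not None else x
            h = h + shortcut
        return h.relu()


class AttentionGate(Module):
    """Additive attention over a skip connection.

    The skip tensor x and the (upsampled) decoder gating signal g are projected
    to an intermediate width, summed, and squashed to a per-voxel coefficient
    a in (0, 1); the gated skip is x * a.  With ``edge_features`` the spatial
    gradient magnitude of x joins the projection, biasing the gate toward
    organ boundaries.
    """

    def __init__(self, c_skip: int, c_gate: int, c_int: int,
                 rng: np.random.Generator, edge_features: bool = True):
        self.edge_features = edge_features
        self.w_x = Conv3d(c_skip, c_int, 1, rng)
        self.w_g = Conv3d(c_gate, c_int, 1, rng)
        self.w_e = Conv3d(c_skip, c_int, 1, rng) if edge_features else None
        self.psi = Conv3d(c_int, 1, 1, rng)

    def forward(self, x: Tensor, g: Tensor) -> Tensor:
        s = self.w_x(x) + self.w_g(g)
        if self.w_e is not None:
            s = s + self.w_e(edge_magnitude(x))
        a = self.psi(s.relu()).sigmoid()
        return x * a


class UNet3D(Module):
    """3D U-Net with configurable block type, attention gating and output head.

    ``head`` is ``"softmax"`` for per-voxel class probabilities or
    ``"softplus"`` for a non-negative regression output (attenuation maps).
    """

    def __init__(self, in_channels: int, out_channels: int, initial_neurons: int,
                 depth: int, residual: bool, attention: bool, head: str,
                 rng: np.random.Generator, norm: str = "instance",
                 attention_edge_features: bool = True):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if head not in ("softmax", "softplus", "linear"):
            raise ValueError(f"unknown head {head!r}")
        self.depth = depth
        self.head = head
        self.attention = attention

        widths = [initial_neurons * 2**i for i in range(depth + 1)]
        self.encoders = [
            ConvBlock(in_channels if i == 0 else widths[i - 1], widths[i],
                      residual, rng, norm)
            for i in range(depth)
        ]
        self.bottleneck = ConvBlock(widths[depth - 1], widths[depth], residual, rng, norm)
        self.gates = (
            [AttentionGate(widths[i], widths[i + 1], max(widths[i] // 2, 1), rng,
                           attention_edge_features)
             for i in range(depth)]
            if attention else []
        )
        self.decoders = [
            ConvBlock(widths[i + 1] + widths[i], widths[i], residual, rng, norm)
            for i in range(depth)
        ]
        self.out_conv = Conv3d(widths[0], out_channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        self._check_shape(x.shape)
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = avg_pool3d(h)
        h = self.bottleneck(h)
        for i in reversed(range(self.depth)):
            up = upsample_nearest3d(h)
            skip = skips[i]
            if self.attention:
                skip = self.gates[i](skip, up)
            h = self.decoders[i](concat([skip, up], axis=1))
        out = self.out_conv(h)
        if self.head == "softmax":
            return softmax_channels(out)
        if self.head == "softplus":
            return out.softplus()
        return out

    def _check_shape(self, shape) -> None:
        _, _, d, h, w = shape
        f = 2**self.depth
        if d % f or h % f or w % f:
            raise ValueError(
                f"spatial shape {(d, h, w)} must be divisible by 2^depth = {f}"
            )
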