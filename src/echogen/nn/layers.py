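"""Neural-network modules built on the autograd core."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Module", "Parameter", "Linear", "Conv2d", "ConvTranspose2d",
    "BatchNorm2d", "LayerNormChannel", "LayerNormLast", "Dropout",
    "MultiHeadSelfAttention", "TransformerBlock",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter/module discovery."""

    def __init__(self):
        self.training = True

    def modules(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for v in value:
                    if isinstance(v, Module):
                        yield v
                        yield from v.modules()

    def parameters(self):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield value
        for m in self.modules():
            for name, value in m.__dict__.items():
                if isinstance(value, Parameter):
                    yield value

    def named_parameters(self, prefix=""):
        for name, value in self.__dict__.items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield from v.named_parameters(f"{prefix}{name}.{i}.")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            raise ValueError("state dict does not match module parameters")
        from .autograd import default_dtype
        for name, arr in state.items():
            params[name].data = np.array(arr, dtype=default_dtype())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.w = Parameter(rng.normal(0.0, scale, (n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def forward(self, x):
        return ag.add(ag.matmul(x, self.w), self.b)


def _conv_std(init: str, fan_in: int) -> float:
    # "dcgan": the fixed 0.02 convention of the original Pix2Pix code;
    # "kaiming": fan-in scaled, keeps gradient magnitude through deep
    # decoders (used for the custom ViT variants)
    return 0.02 if init == "dcgan" else float(np.sqrt(2.0 / fan_in))


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator, init: str = "dcgan"):
        super().__init__()
        std = _conv_std(init, c_in * kernel * kernel)
        self.w = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.stride, self.pad = stride, pad

    def forward(self, x):
        return ag.conv2d(x, self.w, self.b, self.stride, self.pad)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 pad: int, rng: np.random.Generator, init: str = "dcgan"):
        super().__init__()
        std = _conv_std(init, c_in * kernel * kernel // (stride * stride))
        self.w = Parameter(rng.normal(0.0, std, (c_in, c_out, kernel, kernel)))
        self.b = Parameter(np.zeros(c_out))
        self.stride, self.pad = stride, pad

    def forward(self, x):
        return ag.conv_transpose2d(x, self.w, self.b, self.stride, self.pad)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros((1, channels, 1, 1))
        self.running_var = np.ones((1, channels, 1, 1))

    def forward(self, x):
        if self.training:
            mu = ag.tmean(x, axis=(0, 2, 3), keepdims=True)
            xc = ag.add(x, ag.mul(mu, -1.0))
            var = ag.tmean(ag.mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data)
            inv = ag.powc(ag.add(var, self.eps), -0.5)
        else:
            xc = ag.add(x, Tensor(-self.running_mean))
            inv = Tensor(1.0 / np.sqrt(self.running_var + self.eps))
        return ag.add(ag.mul(ag.mul(xc, inv), self.gamma), self.beta)


class LayerNormChannel(Module):
    """Layer normalization over the channel axis of an (N, C, H, W) map."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones((1, channels, 1, 1)))
        self.beta = Parameter(np.zeros((1, channels, 1, 1)))
        self.eps = eps

    def forward(self, x):
        mu = ag.tmean(x, axis=1, keepdims=True)
        xc = ag.add(x, ag.mul(mu, -1.0))
        var = ag.tmean(ag.mul(xc, xc), axis=1, keepdims=True)
        inv = ag.powc(ag.add(var, self.eps), -0.5)
        return ag.add(ag.mul(ag.mul(xc, inv), self.gamma), self.beta)


class LayerNormLast(Module):
    """Layer normalization over the last (embedding) axis of token stacks."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        mu = ag.tmean(x, axis=-1, keepdims=True)
        xc = ag.add(x, ag.mul(mu, -1.0))
        var = ag.tmean(ag.mul(xc, xc), axis=-1, keepdims=True)
        inv = ag.powc(ag.add(var, self.eps), -0.5)
        return ag.add(ag.mul(ag.mul(xc, inv), self.gamma), self.beta)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x):
        return ag.dropout(x, self.p, self.rng, self.training)


class MultiHeadSelfAttention(Module):
    def __init__(self, embed_dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if embed_dim % n_heads:
            raise ValueError("embed_dim must divide by n_heads")
        self.h = n_heads
        self.d = embed_dim // n_heads
        self.qkv = Linear(embed_dim, 3 * embed_dim, rng)
        self.proj = Linear(embed_dim, embed_dim, rng)

    def forward(self, x):
        n, t, e = x.shape
        qkv = self.qkv(x)                                  # (N, T, 3E)
        qkv = ag.reshape(qkv, (n, t, 3, self.h, self.d))
        qkv = ag.transpose(qkv, (2, 0, 3, 1, 4))           # (3, N, h, T, d)

        def pick(which):  # select q/k/v with a one-hot contraction
            sel = np.zeros((3, 1, 1, 1, 1))
            sel[which] = 1.0
            return ag.tsum(ag.mul(qkv, Tensor(sel)), axis=0)

        qh, kh, vh = pick(0), pick(1), pick(2)             # (N, h, T, d)
        scores = ag.mul(ag.matmul(qh, ag.transpose(kh, (0, 1, 3, 2))),
                        1.0 / np.sqrt(self.d))
        attn = ag.softmax(scores, axis=-1)
        ctx = ag.matmul(attn, vh)                          # (N, h, T, d)
        ctx = ag.reshape(ag.transpose(ctx, (0, 2, 1, 3)), (n, t, e))
        return self.proj(ctx)


class TransformerBlock(Module):
    """Pre-norm encoder block: LN -> MHSA -> residual; LN -> MLP -> residual."""

    def __init__(self, embed_dim: int, n_heads: int, mlp_ratio: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.ln1 = LayerNormLast(embed_dim)
        self.attn = MultiHeadSelfAttention(embed_dim, n_heads, rng)
        self.ln2 = LayerNormLast(embed_dim)
        self.fc1 = Linear(embed_dim, mlp_ratio * embed_dim, rng)
        self.fc2 = Linear(mlp_ratio * embed_dim, embed_dim, rng)
        self.drop = Dropout(dropout, rng)

    def forward(self, x):
        x = ag.add(x, self.attn(self.ln1(x)))
        h = self.fc2(ag.gelu(self.fc1(self.ln2(x))))
        return ag.add(x, self.drop(h))
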