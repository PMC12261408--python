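"""Neural layers for the convolution-transformer encoder, plus Adam.

All layers hold their parameters as :class:`~atcpred.nn.autodiff.Tensor`
objects with ``requires_grad=True`` and expose ``parameters()`` for the
optimizer.  Initialisation follows the usual fan-in scaling (Glorot for
square projections, He for the ReLU feed-forward) and is fully determined by
the generator passed in.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "Conv1dTokenizer",
    "MultiHeadSelfAttention",
    "FeedForward",
    "TransformerBlock",
    "Linear",
    "sinusoidal_positions",
    "Adam",
    "n_tokens",
]


def n_tokens(length: int, kernel: int, stride: int) -> int:
    """Number of convolution output positions for a 1-D input of ``length``."""
    if length < kernel:
        raise ValueError(f"input length {length} shorter than kernel {kernel}")
    return (length - kernel) // stride + 1


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    def __init__(self, rng: np.random.Generator, fan_in: int, fan_out: int, relu_gain=False):
        if relu_gain:
            w = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        else:
            w = _glorot(rng, fan_in, fan_out)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(fan_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Conv1dTokenizer:
    """1-D convolution over the 2-row feature matrix, expressed as im2col + matmul.

    The two feature rows act as input channels; a kernel of width ``kernel``
    slides along the column axis with the given stride and maps each window
    to a ``width``-dimensional token.
    """

    def __init__(self, rng: np.random.Generator, kernel: int, stride: int, width: int,
                 in_channels: int = 2):
        self.kernel, self.stride, self.width = kernel, stride, width
        self.in_channels = in_channels
        self.proj = Linear(rng, in_channels * kernel, width)

    def patches(self, x: np.ndarray) -> np.ndarray:
        """(B, C_in, L_in) -> (B, L_out, C_in * kernel), no gradient needed."""
        b, c, length = x.shape
        L = n_tokens(length, self.kernel, self.stride)
        s0, s1, s2 = x.strides
        windows = np.lib.stride_tricks.as_strided(
            x, shape=(b, c, L, self.kernel), strides=(s0, s1, s2 * self.stride, s2),
            writeable=False,
        )
        # (B, L, C_in, kernel) flattened so channel-major matches weight layout
        return np.ascontiguousarray(windows.transpose(0, 2, 1, 3)).reshape(b, L, c * self.kernel)

    def __call__(self, x: np.ndarray) -> Tensor:
        return self.proj(Tensor(self.patches(np.asarray(x, dtype=np.float64))))

    def parameters(self) -> list[Tensor]:
        return self.proj.parameters()


def sinusoidal_positions(length: int, width: int) -> np.ndarray:
    """Classic fixed sine/cosine positional-encoding table (length, width)."""
    pos = np.arange(length)[:, None]
    i = np.arange(width)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / width)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


class MultiHeadSelfAttention:
    """Scaled dot-product self-attention with ``n_heads`` parallel heads."""

    def __init__(self, rng: np.random.Generator, width: int, n_heads: int):
        if width % n_heads:
            raise ValueError(f"width {width} not divisible by {n_heads} heads")
        self.width, self.n_heads = width, n_heads
        self.d_k = width // n_heads
        self.wq = Linear(rng, width, width)
        self.wk = Linear(rng, width, width)
        self.wv = Linear(rng, width, width)
        self.wo = Linear(rng, width, width)

    def _split(self, x: Tensor, b: int, L: int) -> Tensor:
        return x.reshape(b, L, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, attn_dropout: float = 0.0,
                 rng: np.random.Generator | None = None) -> Tensor:
        b, L, _ = x.shape
        q = self._split(self.wq(x), b, L)
        k = self._split(self.wk(x), b, L)
        v = self._split(self.wv(x), b, L)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_k))
        attn = scores.softmax(axis=-1).dropout(attn_dropout, rng)
        z = (attn @ v).transpose(0, 2, 1, 3).reshape(b, L, self.width)
        return self.wo(z)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """(B, heads, L, L) softmax weights, for inspection/testing."""
        b, L, _ = x.shape
        q = self._split(self.wq(x), b, L)
        k = self._split(self.wk(x), b, L)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_k))
        return scores.softmax(axis=-1).data

    def parameters(self) -> list[Tensor]:
        return [p for lin in (self.wq, self.wk, self.wv, self.wo) for p in lin.parameters()]


class FeedForward:
    """Two linear maps with a ReLU between them."""

    def __init__(self, rng: np.random.Generator, width: int, hidden: int):
        self.fc1 = Linear(rng, width, hidden, relu_gain=True)
        self.fc2 = Linear(rng, hidden, width)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())

    def parameters(self) -> list[Tensor]:
        return self.fc1.parameters() + self.fc2.parameters()


class TransformerBlock:
    """Post-norm encoder block: x = LN(x + MHSA(x)); x = LN(x + FFN(x))."""

    def __init__(self, rng: np.random.Generator, width: int, n_heads: int, ffn_hidden: int,
                 dropout: float = 0.1):
        self.attn = MultiHeadSelfAttention(rng, width, n_heads)
        self.ffn = FeedForward(rng, width, ffn_hidden)
        self.dropout = dropout
        self.ln1_g = Tensor(np.ones(width), requires_grad=True)
        self.ln1_b = Tensor(np.zeros(width), requires_grad=True)
        self.ln2_g = Tensor(np.ones(width), requires_grad=True)
        self.ln2_b = Tensor(np.zeros(width), requires_grad=True)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        a = self.attn(x, self.dropout, rng).dropout(self.dropout, rng)
        x = (x + a).layer_norm(self.ln1_g, self.ln1_b)
        f = self.ffn(x).dropout(self.dropout, rng)
        return (x + f).layer_norm(self.ln2_g, self.ln2_b)

    def parameters(self) -> list[Tensor]:
        return (self.attn.parameters() + self.ffn.parameters()
                + [self.ln1_g, self.ln1_b, self.ln2_g, self.ln2_b])


class Adam:
    """Adaptive-moment gradient descent (bias-corrected first/second moments)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
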