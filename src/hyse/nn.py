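"""A minimal numpy convolutional-network engine.

Implements exactly what the classifiers here need: 2-D convolution via
im2col, ReLU, max-pooling, dropout, a per-position softmax cross-entropy
loss, and momentum SGD with L2 weight decay. All layers operate on arrays
of shape ``(batch, channels, H, W)``; fully connected stages are expressed
as valid convolutions spanning the remaining spatial extent, which lets the
same machinery serve both the patch-input (pixel-wise) network and the
slice-wise network with its dense per-line-pixel output.

Gradients are exact (verified against finite differences in the test
suite); no autodiff framework is involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass
class Param:
    """A trainable array with its gradient and an L2-decay flag."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)
    decay: bool = True

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """2-D convolution (cross-correlation), stride 1, 'valid' or 'same'."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        ksize: tuple[int, int],
        rng: np.random.Generator,
        padding: str = "valid",
    ) -> None:
        if padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        kh, kw = ksize
        self.in_ch, self.out_ch, self.kh, self.kw = in_ch, out_ch, kh, kw
        self.padding = padding
        std = np.sqrt(2.0 / (in_ch * kh * kw))  # He initialization for ReLU nets
        self.w = Param(rng.normal(0.0, std, size=(out_ch, in_ch, kh, kw)))
        self.b = Param(np.zeros(out_ch), decay=False)
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        if self.padding == "valid":
            return x, (0, 0)
        ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (ph, self.kh - 1 - ph), (pw, self.kw - 1 - pw)))
        return xp, (ph, pw)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xp, _ = self._pad(x)
        B = x.shape[0]
        # windows: (B, C, Ho, Wo, kh, kw)
        win = sliding_window_view(xp, (self.kh, self.kw), axis=(2, 3))
        Ho, Wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, -1)
        wmat = self.w.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b.value
        out = out.reshape(B, Ho, Wo, self.out_ch).transpose(0, 3, 1, 2)
        self._cache = (cols, x.shape, xp.shape, Ho, Wo)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, xp_shape, Ho, Wo = self._cache
        B = x_shape[0]
        dmat = dout.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, self.out_ch)
        wmat = self.w.value.reshape(self.out_ch, -1)
        self.w.grad += (dmat.T @ cols).reshape(self.w.value.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ wmat).reshape(B, Ho, Wo, self.in_ch, self.kh, self.kw)
        dxp = np.zeros(xp_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                dxp[:, :, i : i + Ho, j : j + Wo] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        if self.padding == "same":
            ph, pw = (self.kh - 1) // 2, (self.kw - 1) // 2
            H, W = x_shape[2], x_shape[3]
            return dxp[:, :, ph : ph + H, pw : pw + W]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing rows/cols are cropped."""

    def __init__(self, pool: tuple[int, int]) -> None:
        self.ph, self.pw = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        Ho, Wo = H // self.ph, W // self.pw
        xc = x[:, :, : Ho * self.ph, : Wo * self.pw]
        win = xc.reshape(B, C, Ho, self.ph, Wo, self.pw).transpose(0, 1, 2, 4, 3, 5)
        flat = win.reshape(B, C, Ho, Wo, self.ph * self.pw)
        self._argmax = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        Ho, Wo = H // self.ph, W // self.pw
        dflat = np.zeros((B, C, Ho, Wo, self.ph * self.pw))
        np.put_along_axis(dflat, self._argmax[..., None], dout[..., None], axis=-1)
        dxc = dflat.reshape(B, C, Ho, Wo, self.ph, self.pw).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros(self._in_shape)
        dx[:, :, : Ho * self.ph, : Wo * self.pw] = dxc.reshape(
            B, C, Ho * self.ph, Wo * self.pw
        )
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over batch and spatial positions.

    ``logits``: (B, K, H, W); ``labels``: integer (B, H, W). Returns the
    loss and its gradient with respect to the logits.
    """
    probs = softmax(logits, axis=1)
    B, K, H, W = logits.shape
    n = B * H * W
    idx = np.ogrid[:B, :H, :W]
    picked = probs[idx[0], labels, idx[1], idx[2]]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    grad = probs.copy()
    grad[idx[0], labels, idx[1], idx[2]] -= 1.0
    return loss, grad / n


class MomentumSGD:
    """Classic momentum SGD; L2 decay added to gradients of flagged params."""

    def __init__(
        self,
        params: list[Param],
        lr: float,
        momentum: float = 0.9,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            g = p.grad + (self.weight_decay * p.value if p.decay else 0.0)
            v *= self.momentum
            v -= self.lr * g
            p.value += v


def l2_penalty(params: list[Param], coefficient: float) -> float:
    if coefficient == 0.0:
        return 0.0
    return float(
        0.5 * coefficient * sum(np.sum(p.value**2) for p in params if p.decay)
    )
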