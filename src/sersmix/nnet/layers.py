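"""1-D convolutional layers with explicit forward/backward passes.

All layers operate on arrays of shape ``(batch, channels, length)`` except
``Linear`` and ``GlobalAvgPool1d`` outputs, which are ``(batch, features)``.
Each layer caches what its backward pass needs during forward; ``backward``
accumulates parameter gradients into ``Param.grad`` and returns the gradient
with respect to its input.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    train_mode: bool = True

    def params(self) -> list[Param]:
        return []

    def set_mode(self, train: bool) -> None:
        self.train_mode = train

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Strided sliding-window view of shape (B, C, L_out, k)."""
    B, C, L = x.shape
    L_out = (L - k) // stride + 1
    sB, sC, sL = x.strides
    return np.lib.stride_tricks.as_strided(
        x, shape=(B, C, L_out, k), strides=(sB, sC, stride * sL, sL), writeable=False
    )


class Conv1d(Layer):
    """Cross-correlation with symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 bias: bool = True, name: str = "conv"):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = c_in * kernel
        w = rng.standard_normal((c_out, c_in, kernel)) * np.sqrt(2.0 / fan_in)
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b") if bias else None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._xp = x
        cols = _windows(x, self.kernel, self.stride)            # (B, C, Lo, k)
        B, C, Lo, k = cols.shape
        self._cols = cols.transpose(0, 2, 1, 3).reshape(B, Lo, C * k)
        wmat = self.w.value.reshape(self.c_out, C * k)
        out = self._cols @ wmat.T                               # (B, Lo, c_out)
        if self.b is not None:
            out += self.b.value
        return out.transpose(0, 2, 1)                           # (B, c_out, Lo)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, _, Lo = dout.shape
        d = dout.transpose(0, 2, 1)                             # (B, Lo, c_out)
        if self.b is not None:
            self.b.grad += d.sum(axis=(0, 1))
        dmat = d.reshape(B * Lo, self.c_out)
        cols = self._cols.reshape(B * Lo, -1)
        self.w.grad += (dmat.T @ cols).reshape(self.w.value.shape)
        wmat = self.w.value.reshape(self.c_out, -1)
        dcols = (dmat @ wmat).reshape(B, Lo, self.c_in, self.kernel)
        dcols = dcols.transpose(0, 2, 1, 3)                     # (B, C, Lo, k)
        dxp = np.zeros_like(self._xp)
        for j in range(self.kernel):
            dxp[:, :, j : j + Lo * self.stride : self.stride] += dcols[:, :, :, j]
        if self.pad:
            return dxp[:, :, self.pad : dxp.shape[2] - self.pad]
        return dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.train_mode:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None]) * self._invstd[:, None]
        return self.gamma.value[:, None] * self._xhat + self.beta.value[:, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.gamma.grad += (dout * self._xhat).sum(axis=(0, 2))
        self.beta.grad += dout.sum(axis=(0, 2))
        g = self.gamma.value[:, None] * self._invstd[:, None]
        if not self.train_mode:
            return dout * g
        N = dout.shape[0] * dout.shape[2]
        dxhat = dout * self.gamma.value[:, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2), keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True) / N
        )
        return term * self._invstd[:, None]


class Identity(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout


class ReLU(Layer):
    """Rectifier with optional leak so sub-threshold responses survive."""

    def __init__(self, slope: float = 0.0):
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * np.where(self._mask, 1.0, self.slope)


class MaxPool1d(Layer):
    def __init__(self, kernel: int, stride: int, pad: int = 0):
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)),
                       constant_values=-np.inf)
        self._shape = x.shape
        win = _windows(x, self.kernel, self.stride)
        self._argmax = win.argmax(axis=3)
        return win.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, Lo = dout.shape
        dxp = np.zeros(self._shape)
        # scatter each window's gradient onto its argmax position
        base = self.stride * np.arange(Lo)
        idx = base[None, None, :] + self._argmax          # (B, C, Lo) absolute pos
        bi = np.arange(B)[:, None, None]
        ci = np.arange(C)[None, :, None]
        np.add.at(dxp, (bi, ci, idx), dout)
        if self.pad:
            return dxp[:, :, self.pad : dxp.shape[2] - self.pad]
        return dxp


class GlobalAvgPool1d(Layer):
    """(B, C, L) -> (B, C) by averaging over length."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.repeat(dout[:, :, None], self._L, axis=2) / self._L


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 name: str = "linear"):
        rng = rng or np.random.default_rng(0)
        w = rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in)
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(d_out), f"{name}.b")

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for l in self.layers for p in l.params()]

    def set_mode(self, train: bool) -> None:
        self.train_mode = train
        for l in self.layers:
            l.set_mode(train)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class ResidualBlock1d(Layer):
    """Basic residual unit: conv3-BN-ReLU-conv3-BN plus (projected) shortcut."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1,
                 rng: np.random.Generator | None = None, name: str = "res",
                 batch_norm: bool = True, relu_slope: float = 0.0):
        rng = rng or np.random.default_rng(0)
        use_bias = not batch_norm

        def norm(tag: str):
            return BatchNorm1d(c_out, name=f"{name}.{tag}") if batch_norm else Identity()

        self.conv1 = Conv1d(c_in, c_out, 3, stride=stride, rng=rng, bias=use_bias,
                            name=f"{name}.conv1")
        self.bn1 = norm("bn1")
        self.relu1 = ReLU(relu_slope)
        self.conv2 = Conv1d(c_out, c_out, 3, stride=1, rng=rng, bias=use_bias,
                            name=f"{name}.conv2")
        self.bn2 = norm("bn2")
        self.relu2 = ReLU(relu_slope)
        if stride != 1 or c_in != c_out:
            self.proj = Conv1d(c_in, c_out, 1, stride=stride, pad=0, rng=rng,
                               bias=False, name=f"{name}.proj")
            self.proj_bn = norm("projbn")
        else:
            self.proj = None
            self.proj_bn = None

    def _sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2]
        if self.proj is not None:
            subs += [self.proj, self.proj_bn]
        return subs

    def params(self) -> list[Param]:
        return [p for l in self._sublayers() for p in l.params()]

    def set_mode(self, train: bool) -> None:
        self.train_mode = train
        for l in self._sublayers():
            l.set_mode(train)

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.bn2(self.conv2(self.relu1(self.bn1(self.conv1(x)))))
        if self.proj is not None:
            shortcut = self.proj_bn(self.proj(x))
        else:
            shortcut = x
        return self.relu2(out + shortcut)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dout)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        if self.proj is not None:
            dshort = self.proj.backward(self.proj_bn.backward(d))
        else:
            dshort = d
        return dmain + dshort
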