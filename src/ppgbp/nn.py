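"""Minimal numpy neural-network engine for 1-D biosignal regression.

Layers operate on arrays of shape ``(batch, length, channels)`` (recurrent
and convolutional) or ``(batch, features)`` (dense) and implement explicit
forward/backward passes; gradients are checked against finite differences
in the test suite.  Supplies everything the architecture zoo needs:
1-D convolution, max/global-average pooling, batch normalization,
bidirectional LSTM, GRU, dense layers, residual and parallel containers,
a fixed log-magnitude spectrogram featurizer, and an Adam optimizer.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "Conv1d", "ReLU", "MaxPool1d",
    "GlobalAvgPool1d", "Flatten", "BatchNorm1d", "LSTM", "GRU",
    "Residual", "Parallel", "Spectrogram", "Sequential", "Adam",
    "mse_loss_and_grad", "fingerprint_params",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.w = Param(_he_init(rng, (n_in, n_out), n_in), f"{name}.w")
        self.b = Param(np.zeros(n_out), f"{name}.b")
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad):
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self):
        return [self.w, self.b]


class Conv1d(Layer):
    """1-D convolution on (B, L, C_in); 'valid' or 'same' padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator, padding: str = "same",
                 name: str = "conv"):
        self.k, self.stride, self.padding = kernel, stride, padding
        self.c_in, self.c_out = c_in, c_out
        self.w = Param(_he_init(rng, (kernel * c_in, c_out), kernel * c_in),
                       f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cols = None
        self._xshape = None
        self._pads = (0, 0)

    def _pad(self, length: int) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        l_out = -(-length // self.stride)  # ceil
        total = max((l_out - 1) * self.stride + self.k - length, 0)
        return total // 2, total - total // 2

    def forward(self, x, train=False):
        b, length, _ = x.shape
        p0, p1 = self._pad(length)
        self._pads = (p0, p1)
        xp = np.pad(x, ((0, 0), (p0, p1), (0, 0))) if (p0 or p1) else x
        self._xshape = xp.shape
        view = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        # view: (B, Lv, C, k) -> strided -> (B, Lo, k*C)
        view = view[:, ::self.stride]
        cols = view.transpose(0, 1, 3, 2).reshape(b, view.shape[1], -1)
        self._cols = cols
        return cols @ self.w.value + self.b.value

    def backward(self, grad):
        b, l_out, _ = grad.shape
        self.w.grad += np.einsum("blf,blo->fo", self._cols, grad)
        self.b.grad += grad.sum(axis=(0, 1))
        gcols = (grad @ self.w.value.T).reshape(b, l_out, self.k, self.c_in)
        dxp = np.zeros(self._xshape)
        for j in range(self.k):
            dxp[:, j:j + self.stride * l_out:self.stride] += gcols[:, :, j]
        p0, p1 = self._pads
        return dxp[:, p0:dxp.shape[1] - p1] if (p0 or p1) else dxp

    def params(self):
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Layer):
    def __init__(self, kernel: int, stride: int | None = None):
        self.k = kernel
        self.stride = stride or kernel

    def forward(self, x, train=False):
        b, length, c = x.shape
        l_out = (length - self.k) // self.stride + 1
        view = np.lib.stride_tricks.sliding_window_view(x, self.k, axis=1)
        view = view[:, ::self.stride][:, :l_out]      # (B, Lo, C, k)
        self._arg = np.argmax(view, axis=-1)          # (B, Lo, C)
        self._xshape = x.shape
        return np.max(view, axis=-1)

    def backward(self, grad):
        b, l_out, c = grad.shape
        dx = np.zeros(self._xshape)
        bi, li, ci = np.meshgrid(np.arange(b), np.arange(l_out), np.arange(c),
                                 indexing="ij")
        pos = li * self.stride + self._arg
        np.add.at(dx, (bi, pos, ci), grad)
        return dx


class GlobalAvgPool1d(Layer):
    def forward(self, x, train=False):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._length, axis=1) / self._length


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and time axes."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad):
        axes, n = self._axes, self._n
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value
        return self._istd / n * (
            n * dxhat - dxhat.sum(axis=axes)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes))

    def params(self):
        return [self.gamma, self.beta]


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class _LSTMDirection:
    """One direction of an LSTM over (B, T, C)."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool, name: str):
        h = hidden
        scale_w = np.sqrt(1.0 / c_in)
        scale_u = np.sqrt(1.0 / h)
        self.w = Param(rng.uniform(-scale_w, scale_w, (c_in, 4 * h)), f"{name}.w")
        self.u = Param(rng.uniform(-scale_u, scale_u, (h, 4 * h)), f"{name}.u")
        self.b = Param(np.zeros(4 * h), f"{name}.b")
        self.h, self.reverse = h, reverse

    def forward(self, x):
        b, t, _ = x.shape
        h = self.h
        xs = x[:, ::-1] if self.reverse else x
        hs = np.zeros((t + 1, b, h))
        cs = np.zeros((t + 1, b, h))
        gates = np.zeros((t, b, 4 * h))
        pre = xs.transpose(1, 0, 2) @ self.w.value + self.b.value
        for step in range(t):
            z = pre[step] + hs[step] @ self.u.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            cs[step + 1] = f * cs[step] + i * g
            hs[step + 1] = o * np.tanh(cs[step + 1])
            gates[step] = np.concatenate([i, f, g, o], axis=1)
        self._cache = (xs, hs, cs, gates)
        out = hs[1:].transpose(1, 0, 2)
        return out[:, ::-1] if self.reverse else out

    def backward(self, grad):
        xs, hs, cs, gates = self._cache
        t, b, h = gates.shape[0], gates.shape[1], self.h
        gseq = (grad[:, ::-1] if self.reverse else grad).transpose(1, 0, 2)
        dxs = np.zeros_like(xs)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        dw = np.zeros_like(self.w.value)
        du = np.zeros_like(self.u.value)
        db = np.zeros_like(self.b.value)
        for step in range(t - 1, -1, -1):
            i, f, g, o = (gates[step][:, :h], gates[step][:, h:2 * h],
                          gates[step][:, 2 * h:3 * h], gates[step][:, 3 * h:])
            dh = gseq[step] + dh_next
            tc = np.tanh(cs[step + 1])
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * cs[step]
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dw += xs[:, step].T @ dz
            du += hs[step].T @ dz
            db += dz.sum(axis=0)
            dxs[:, step] = dz @ self.w.value.T
            dh_next = dz @ self.u.value.T
            dc_next = dc * f
        self.w.grad += dw
        self.u.grad += du
        self.b.grad += db
        return dxs[:, ::-1] if self.reverse else dxs

    def params(self):
        return [self.w, self.u, self.b]


class LSTM(Layer):
    """(Bidirectional) LSTM; returns full sequence or last state."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator,
                 bidirectional: bool = True, return_sequences: bool = True,
                 name: str = "lstm"):
        self.fwd = _LSTMDirection(c_in, hidden, rng, False, f"{name}.fwd")
        self.bwd = (_LSTMDirection(c_in, hidden, rng, True, f"{name}.bwd")
                    if bidirectional else None)
        self.return_sequences = return_sequences
        self.hidden = hidden

    def forward(self, x, train=False):
        out = self.fwd.forward(x)
        if self.bwd is not None:
            out = np.concatenate([out, self.bwd.forward(x)], axis=-1)
        self._tb = (x.shape[0], x.shape[1])
        if self.return_sequences:
            return out
        # last valid state of each direction: forward at T-1, backward at 0
        if self.bwd is None:
            return out[:, -1]
        h = self.hidden
        return np.concatenate([out[:, -1, :h], out[:, 0, h:]], axis=-1)

    def backward(self, grad):
        b, t = self._tb
        h = self.hidden
        if self.return_sequences:
            gseq = grad
        else:
            width = 2 * h if self.bwd is not None else h
            gseq = np.zeros((b, t, width))
            gseq[:, -1, :h] = grad[:, :h]
            if self.bwd is not None:
                gseq[:, 0, h:] = grad[:, h:]
        dx = self.fwd.backward(gseq[..., :h])
        if self.bwd is not None:
            dx = dx + self.bwd.backward(gseq[..., h:])
        return dx

    def params(self):
        out = self.fwd.params()
        if self.bwd is not None:
            out += self.bwd.params()
        return out


class GRU(Layer):
    """Unidirectional GRU; returns the last hidden state."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator,
                 name: str = "gru"):
        h = hidden
        sw, su = np.sqrt(1.0 / c_in), np.sqrt(1.0 / h)
        self.w = Param(rng.uniform(-sw, sw, (c_in, 3 * h)), f"{name}.w")
        self.u = Param(rng.uniform(-su, su, (h, 3 * h)), f"{name}.u")
        self.b = Param(np.zeros(3 * h), f"{name}.b")
        self.h = h

    def forward(self, x, train=False):
        b, t, _ = x.shape
        h = self.h
        hs = np.zeros((t + 1, b, h))
        cache = []
        pre = x.transpose(1, 0, 2) @ self.w.value + self.b.value
        for step in range(t):
            uh = hs[step] @ self.u.value
            z = _sigmoid(pre[step][:, :h] + uh[:, :h])
            r = _sigmoid(pre[step][:, h:2 * h] + uh[:, h:2 * h])
            n = np.tanh(pre[step][:, 2 * h:] + r * uh[:, 2 * h:])
            hs[step + 1] = (1.0 - z) * n + z * hs[step]
            cache.append((z, r, n, uh[:, 2 * h:]))
        self._cache = (x, hs, cache)
        return hs[-1]

    def backward(self, grad):
        x, hs, cache = self._cache
        b, t, _ = x.shape
        h = self.h
        dx = np.zeros_like(x)
        dh = grad.copy()
        for step in range(t - 1, -1, -1):
            z, r, n, uh_n = cache[step]
            dz = dh * (hs[step] - n)
            dn = dh * (1.0 - z)
            dpre_n = dn * (1.0 - n ** 2)
            dr = dpre_n * uh_n
            dpre_z = dz * z * (1 - z)
            dpre_r = dr * r * (1 - r)
            dzrn = np.concatenate([dpre_z, dpre_r, dpre_n], axis=1)
            self.w.grad += x[:, step].T @ dzrn
            self.b.grad += dzrn.sum(axis=0)
            dx[:, step] = dzrn @ self.w.value.T
            du_in = np.concatenate([dpre_z, dpre_r, dpre_n * r], axis=1)
            self.u.grad += hs[step].T @ du_in
            dh = dh * z + du_in @ self.u.value.T
        return dx

    def params(self):
        return [self.w, self.u, self.b]


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class Residual(Layer):
    """y = main(x) + shortcut(x), with an optional projection shortcut."""

    def __init__(self, main: Sequential, shortcut: Sequential | None = None):
        self.main = main
        self.shortcut = shortcut

    def forward(self, x, train=False):
        y = self.main.forward(x, train=train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train=train)
        return y + s

    def backward(self, grad):
        dx = self.main.backward(grad)
        ds = grad if self.shortcut is None else self.shortcut.backward(grad)
        return dx + ds

    def params(self):
        out = self.main.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out


class Spectrogram(Layer):
    """Fixed log-magnitude spectrogram of channel 0; not trainable.

    Output shape (B, frames, freq_bins).  Sits at the model input in a
    parallel branch, so no gradient needs to flow through it.
    """

    def __init__(self, frame: int = 125, hop: int = 62, n_freq: int = 33):
        self.frame, self.hop, self.n_freq = frame, hop, n_freq
        self._window = np.hanning(frame)

    def forward(self, x, train=False):
        self._xshape = x.shape
        sig = x[..., 0]
        b, length = sig.shape
        n_frames = max(1, (length - self.frame) // self.hop + 1)
        idx = (np.arange(self.frame)[None, :]
               + self.hop * np.arange(n_frames)[:, None])
        frames = sig[:, idx] * self._window          # (B, F, frame)
        spec = np.abs(np.fft.rfft(frames, axis=-1))[..., :self.n_freq]
        return np.log1p(spec)

    def backward(self, grad):
        return np.zeros(self._xshape)


class Parallel(Layer):
    """Run branches on the same input, align time axes, concat channels.

    Branch outputs must be (B, T_i, C_i); shorter/longer sequences are
    aligned to branch 0's length by nearest-index resampling.
    """

    def __init__(self, branches: list[Sequential]):
        self.branches = branches

    def forward(self, x, train=False):
        outs = [br.forward(x, train=train) for br in self.branches]
        t0 = outs[0].shape[1]
        self._maps = []
        aligned = []
        for out in outs:
            t_i = out.shape[1]
            idx = np.minimum((np.arange(t0) * t_i) // t0, t_i - 1)
            self._maps.append((t_i, idx))
            aligned.append(out[:, idx])
        self._widths = [o.shape[-1] for o in aligned]
        return np.concatenate(aligned, axis=-1)

    def backward(self, grad):
        dx = None
        lo = 0
        for br, (t_i, idx), width in zip(self.branches, self._maps, self._widths):
            g = grad[..., lo:lo + width]
            lo += width
            gfull = np.zeros((grad.shape[0], t_i, width))
            np.add.at(gfull, (slice(None), idx), g)
            d = br.backward(gfull)
            dx = d if dx is None else dx + d
        return dx

    def params(self):
        return [p for br in self.branches for p in br.params()]


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss_and_grad(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements and its gradient w.r.t. pred."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size


def fingerprint_params(params: list[Param]) -> str:
    """SHA-256 over the exact bytes of a parameter list (order-sensitive)."""
    digest = hashlib.sha256()
    for p in params:
        digest.update(p.name.encode())
        digest.update(np.ascontiguousarray(p.value).tobytes())
    return digest.hexdigest()
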