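"""Neural layers and the Adam optimizer on top of :mod:`hcsnet.autograd`.

Covers exactly what the movement-prediction network needs: linear maps, a
single-layer LSTM, 1-D same-padded convolution, batch normalization, average
pooling, a depthwise cross-channel mixing layer, and Adam with the standard
defaults. All parameter initialization is driven by an explicit
``numpy.random.Generator`` so builds are reproducible.
"""

from __future__ import annotations

import numpy as np

from hcsnet import autograd as ag
from hcsnet.autograd import Tensor


class Module:
    """Base: tracks parameters and train/eval mode."""

    def __init__(self):
        self._params: list[Tensor] = []
        self._children: list[Module] = []
        self.training = True

    def add_param(self, data: np.ndarray) -> Tensor:
        p = Tensor(data, requires_grad=True)
        self._params.append(p)
        return p

    def add_child(self, m: "Module") -> "Module":
        self._children.append(m)
        return m

    def parameters(self) -> list[Tensor]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def train(self, mode: bool = True) -> None:
        self.training = mode
        for c in self._children:
            c.train(mode)

    def eval(self) -> None:
        self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        """Parameter arrays plus any running buffers, in a stable order."""
        out = [p.data for p in self._params]
        for c in self._children:
            out.extend(c.state_arrays())
        return out

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        flat = self.state_arrays()
        if len(flat) != len(arrays):
            raise ValueError(f"state mismatch: have {len(flat)} arrays, got {len(arrays)}")
        for dst, src in zip(flat, arrays):
            if dst.shape != src.shape:
                raise ValueError(f"state shape mismatch: {dst.shape} vs {src.shape}")
            dst[...] = src

    def param_checksum(self) -> float:
        return float(sum(np.sum(a) for a in self.state_arrays()))


def _uniform_fan_in(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.add_param(_uniform_fan_in(rng, (n_in, n_out), n_in))
        self.b = self.add_param(_uniform_fan_in(rng, (n_out,), n_in))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LSTM(Module):
    """Single-layer unidirectional LSTM; returns the full hidden sequence.

    Gate order in the packed weight matrix is (i, f, g, o); the forget-gate
    bias starts at 1, the usual remedy against early gradient vanishing.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.w = self.add_param(_uniform_fan_in(rng, (n_in + hidden, 4 * hidden), n_in + hidden))
        b = _uniform_fan_in(rng, (4 * hidden,), n_in + hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = self.add_param(b)

    def forward(self, x: Tensor) -> Tensor:
        """(N, T, D) -> (N, H, T) hidden-state sequence."""
        return lstm_seq(x, self.w, self.b, self.hidden)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def lstm_seq(x: Tensor, w: Tensor, b: Tensor, hidden: int) -> Tensor:
    """Fused LSTM over a (N, T, D) batch -> (N, H, T) hidden sequence.

    One graph node for the whole recurrence; the backward pass replays the
    standard cell equations in reverse with cached activations.
    """
    n, t_len, d = x.data.shape
    hs = np.empty((t_len, n, hidden))
    cache = []
    h = np.zeros((n, hidden))
    c = np.zeros((n, hidden))
    wd, bd = w.data, b.data
    for t in range(t_len):
        cat = np.concatenate([x.data[:, t, :], h], axis=1)
        z = cat @ wd + bd
        i = _sigmoid(z[:, :hidden])
        f = _sigmoid(z[:, hidden : 2 * hidden])
        g = np.tanh(z[:, 2 * hidden : 3 * hidden])
        o = _sigmoid(z[:, 3 * hidden :])
        c_prev = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[t] = h
        cache.append((cat, i, f, g, o, c_prev, tc))
    out = Tensor(hs.transpose(1, 2, 0), parents=(x, w, b))

    def bwd(grad):
        gh_seq = grad.transpose(2, 0, 1)  # (T, N, H)
        dw = np.zeros_like(wd)
        db = np.zeros_like(bd)
        dx = np.empty_like(x.data)
        dh = np.zeros((n, hidden))
        dc = np.zeros((n, hidden))
        for t in range(t_len - 1, -1, -1):
            cat, i, f, g, o, c_prev, tc = cache[t]
            dht = gh_seq[t] + dh
            do = dht * tc
            dc = dc + dht * o * (1 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dw += cat.T @ dz
            db += dz.sum(axis=0)
            dcat = dz @ wd.T
            dx[:, t, :] = dcat[:, :d]
            dh = dcat[:, d:]
            dc = dc * f
        if x.requires_grad:
            x._accum(dx)
        if w.requires_grad:
            w._accum(dw)
        if b.requires_grad:
            b._accum(db)

    out._backward = bwd if out.requires_grad else None
    return out


def conv1d_same(x: Tensor, w: Tensor, b: Tensor | None, pad_left: int, pad_right: int) -> Tensor:
    """Stride-1 zero-padded 1-D convolution: (N, Cin, L) x (Cout, Cin, K) -> (N, Cout, L).

    Internally channels-last with one batched matmul per kernel tap, which is
    far cheaper on CPU than materializing an im2col tensor.
    """
    k = w.data.shape[2]
    n, c_in, l = x.data.shape
    c_out = w.data.shape[0]
    # time-major (Tp, N, Cin): tap slices are contiguous views, so every
    # product below is a single strided-free GEMM
    xp = np.zeros((l + k - 1, n, c_in))
    xp[pad_left : pad_left + l] = x.data.transpose(2, 0, 1)
    wt = np.ascontiguousarray(w.data.transpose(2, 1, 0))  # (K, Cin, Cout)
    y2 = xp[0:l].reshape(l * n, c_in) @ wt[0]
    for j in range(1, k):
        y2 += xp[j : j + l].reshape(l * n, c_in) @ wt[j]
    y = y2.reshape(l, n, c_out)
    if b is not None:
        y = y + b.data
    out = Tensor(y.transpose(1, 2, 0), parents=(x, w) if b is None else (x, w, b))

    def bwd(g):
        g2 = np.ascontiguousarray(g.transpose(2, 0, 1)).reshape(l * n, c_out)  # (T*N, Cout)
        if w.requires_grad:
            dw = np.empty((k, c_in, c_out))
            for j in range(k):
                dw[j] = xp[j : j + l].reshape(l * n, c_in).T @ g2
            w._accum(dw.transpose(2, 1, 0))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[j : j + l].reshape(l * n, c_in)[...] += g2 @ wt[j].T
            x._accum(dxp[pad_left : pad_left + l].transpose(1, 2, 0))

    out._backward = bwd if out.requires_grad else None
    return out


class Conv1dSame(Module):
    def __init__(self, c_in: int, c_out: int, kernel_len: int, rng: np.random.Generator):
        super().__init__()
        fan_in = c_in * kernel_len
        self.w = self.add_param(_uniform_fan_in(rng, (c_out, c_in, kernel_len), fan_in))
        self.b = self.add_param(_uniform_fan_in(rng, (c_out,), fan_in))
        self.pad_left = (kernel_len - 1) // 2
        self.pad_right = kernel_len - 1 - self.pad_left

    def forward(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.w, self.b, self.pad_left, self.pad_right)


class BatchNorm1d(Module):
    """Per-feature-map normalization over batch and time, with running stats."""

    def __init__(self, n_maps: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.add_param(np.ones((1, n_maps, 1)))
        self.beta = self.add_param(np.zeros((1, n_maps, 1)))
        self.running_mean = np.zeros((1, n_maps, 1))
        self.running_var = np.ones((1, n_maps, 1))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            xt = ag.reshape(ag.transpose(x, (1, 0, 2)), (x.shape[1], -1))  # (C, N*L)
            mu = ag.reshape(ag.tmean(xt, axis=1), (1, x.shape[1], 1))
            var = ag.reshape(ag.tmean(ag.power(xt - ag.reshape(mu, (x.shape[1], 1)), 2.0), axis=1),
                             (1, x.shape[1], 1))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
            inv = ag.power(var + Tensor(self.eps), -0.5)
            xn = (x - mu) * inv
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xn = (x - Tensor(self.running_mean)) * Tensor(inv)
        return xn * self.gamma + self.beta

    def state_arrays(self) -> list[np.ndarray]:
        return [self.gamma.data, self.beta.data, self.running_mean, self.running_var]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        for dst, src in zip(self.state_arrays(), arrays):
            dst[...] = src


def avg_pool1d(x: Tensor, pool_len: int) -> Tensor:
    """(N, C, L) -> (N, C, L // pool_len); trailing remainder dropped."""
    n, c, l = x.shape
    l2 = (l // pool_len) * pool_len
    if l2 == 0:
        raise ValueError(f"sequence length {l} shorter than pool length {pool_len}")
    if l2 != l:
        x = ag.getitem(x, (slice(None), slice(None), slice(0, l2)))
    x = ag.reshape(x, (n, c, l2 // pool_len, pool_len))
    return ag.tmean(x, axis=3)


class DepthwiseChannelMix(Module):
    """Per-feature-map filters spanning the sEMG-channel axis.

    Input (B, C, F, T): for every feature map f, ``multiplier`` filters mix
    the C channels, giving (B, F * multiplier, T) synergy maps.
    """

    def __init__(self, n_channels: int, n_maps: int, multiplier: int, rng: np.random.Generator):
        super().__init__()
        self.n_maps = n_maps
        self.multiplier = multiplier
        self.w = self.add_param(_uniform_fan_in(rng, (n_maps, multiplier, n_channels), n_channels))
        self.b = self.add_param(_uniform_fan_in(rng, (n_maps * multiplier,), n_channels))

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.w, self.b
        y = np.einsum("bcft,fmc->bfmt", x.data, w.data, optimize=True)
        bsz, f, m, t = y.shape
        y = y.reshape(bsz, f * m, t) + b.data[None, :, None]
        out = Tensor(y, parents=(x, w, b))

        def bwd(g):
            g4 = g.reshape(bsz, f, m, t)
            if w.requires_grad:
                w._accum(np.einsum("bcft,bfmt->fmc", x.data, g4, optimize=True))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                x._accum(np.einsum("bfmt,fmc->bcft", g4, w.data, optimize=True))

        out._backward = bwd if out.requires_grad else None
        return out


class Adam:
    """Adam with the standard defaults (lr 1e-3, betas 0.9/0.999, eps 1e-8)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
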