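"""Neural-network layers on top of the autodiff engine.

Provides the building blocks of the sleep-staging network: linear layers,
strided 1-D convolutions, batch normalisation, a bidirectional LSTM,
dropout, pre-activation residual blocks with global average pooling, and
an Adam optimiser.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, conv1d, stack

NN_DTYPE = np.float32


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    training: bool = True

    def params(self) -> list:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def _modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                yield from (m for m in v if isinstance(m, Module))

    def train(self) -> None:
        self.training = True
        for m in self._modules():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._modules():
            m.eval()

    def _iter_all(self):
        yield self
        for m in self._modules():
            yield from m._iter_all()

    def reset_norm_stats(self) -> None:
        """Zero all running normalisation statistics (before a refresh pass)."""
        for m in self._iter_all():
            if isinstance(m, BatchNorm1d):
                m._ema_mean[:] = 0.0
                m._ema_var[:] = 0.0
                m._steps = 0

    def state_dict(self) -> dict:
        """Copy of all parameters plus normalisation running statistics."""
        norm_state = [
            (m._ema_mean.copy(), m._ema_var.copy(), m._steps)
            for m in self._iter_all()
            if isinstance(m, BatchNorm1d)
        ]
        return {"params": [p.data.copy() for p in self.params()], "norm": norm_state}

    def load_state_dict(self, state: dict) -> None:
        mine = self.params()
        if len(mine) != len(state["params"]):
            raise ValueError("state size mismatch")
        for p, s in zip(mine, state["params"]):
            p.data = s.copy()
        norms = [m for m in self._iter_all() if isinstance(m, BatchNorm1d)]
        if len(norms) != len(state["norm"]):
            raise ValueError("normalisation state mismatch")
        for m, (em, ev, steps) in zip(norms, state["norm"]):
            m._ema_mean, m._ema_var, m._steps = em.copy(), ev.copy(), steps


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / din)
        self.W = Tensor(rng.normal(0, scale, size=(din, dout)).astype(NN_DTYPE), requires_grad=True)
        self.b = Tensor(np.zeros(dout, dtype=NN_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(2.0 / (cin * k))
        self.W = Tensor(rng.normal(0, scale, size=(cout, cin, k)).astype(NN_DTYPE), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=NN_DTYPE), requires_grad=True)
        self.stride = stride
        self.pad = k // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b, stride=self.stride, pad=self.pad)


class BatchNorm1d(Module):
    """Per-channel normalisation over (batch, length) with running stats."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((1, c, 1), dtype=NN_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1), dtype=NN_DTYPE), requires_grad=True)
        # bias-corrected exponential moving averages of batch statistics
        self._ema_mean = np.zeros((1, c, 1), dtype=NN_DTYPE)
        self._ema_var = np.zeros((1, c, 1), dtype=NN_DTYPE)
        self._steps = 0
        self.momentum = momentum
        self.eps = eps

    @property
    def run_mean(self) -> np.ndarray:
        corr = 1.0 - self.momentum ** max(self._steps, 1)
        return self._ema_mean / corr

    @property
    def run_var(self) -> np.ndarray:
        if self._steps == 0:
            return np.ones_like(self._ema_var)
        return self._ema_var / (1.0 - self.momentum**self._steps)

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2), keepdims=True)
            self._steps += 1
            self._ema_mean = self.momentum * self._ema_mean + (1 - self.momentum) * mu.data
            self._ema_var = self.momentum * self._ema_var + (1 - self.momentum) * var.data
        else:
            mu, var = Tensor(self.run_mean), Tensor(self.run_var)
        xh = (x - mu) / (var + self.eps).sqrt()
        return xh * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = ((self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)).astype(x.data.dtype)
        return x * Tensor(mask)


class PreActResBlock(Module):
    """Pre-activation residual block: BN-ReLU-Conv(s2) - BN-ReLU-Conv(s1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator, stride: int = 2):
        self.bn1 = BatchNorm1d(cin)
        self.conv1 = Conv1d(cin, cout, k, stride, rng)
        self.bn2 = BatchNorm1d(cout)
        self.conv2 = Conv1d(cout, cout, k, 1, rng)
        self.skip = Conv1d(cin, cout, 1, stride, rng) if (cin != cout or stride != 1) else None

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(x).relu()
        out = self.conv2(self.bn2(self.conv1(h)).relu())
        shortcut = self.skip(h) if self.skip is not None else x
        return out + shortcut


class ConvEncoder(Module):
    """1-D residual encoder: (N, 900, 3) windows -> (N, feat_dim) vectors.

    A stem convolution followed by pre-activation residual blocks, each
    halving the temporal resolution, then global average pooling, so the
    output width equals the last block's channel count regardless of the
    block count.
    """

    def __init__(self, channels: tuple, kernel: int, rng: np.random.Generator):
        self.stem = Conv1d(3, channels[0], kernel, 1, rng)
        self.blocks = [
            PreActResBlock(channels[i], channels[i + 1], kernel, rng)
            for i in range(len(channels) - 1)
        ]
        self.bn_out = BatchNorm1d(channels[-1])
        self.feat_dim = channels[-1]

    def __call__(self, x: Tensor) -> Tensor:
        h = self.stem(x.transpose(0, 2, 1))
        for blk in self.blocks:
            h = blk(h)
        return self.bn_out(h).relu().mean(axis=2)


class LSTM(Module):
    """Single-layer (optionally bidirectional) LSTM over a (T, din) sequence."""

    def __init__(self, din: int, hidden: int, rng: np.random.Generator, bidirectional: bool = True):
        self.hidden = hidden
        self.bidirectional = bidirectional
        self._dirs = []
        for _ in range(2 if bidirectional else 1):
            s = 1.0 / np.sqrt(hidden)
            Wx = Tensor(rng.uniform(-s, s, size=(din, 4 * hidden)).astype(NN_DTYPE), requires_grad=True)
            Wh = Tensor(rng.uniform(-s, s, size=(hidden, 4 * hidden)).astype(NN_DTYPE), requires_grad=True)
            b = np.zeros(4 * hidden, dtype=NN_DTYPE)
            b[hidden : 2 * hidden] = 1.0  # forget-gate bias
            self._dirs.append((Wx, Wh, Tensor(b, requires_grad=True)))

    def params(self) -> list:
        return [p for trip in self._dirs for p in trip]

    @property
    def out_dim(self) -> int:
        return self.hidden * (2 if self.bidirectional else 1)

    def _run(self, x: Tensor, Wx, Wh, b) -> list:
        T = x.data.shape[0]
        H = self.hidden
        h = Tensor(np.zeros((1, H), dtype=NN_DTYPE))
        c = Tensor(np.zeros((1, H), dtype=NN_DTYPE))
        outs = []
        for t in range(T):
            gates = x[t : t + 1] @ Wx + h @ Wh + b
            i = gates[:, :H].sigmoid()
            f = gates[:, H : 2 * H].sigmoid()
            g = gates[:, 2 * H : 3 * H].tanh()
            o = gates[:, 3 * H :].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs.append(h)
        return outs

    def __call__(self, x: Tensor) -> Tensor:
        fwd = self._run(x, *self._dirs[0])
        if not self.bidirectional:
            return stack(fwd, axis=0).reshape(len(fwd), self.hidden)
        bwd = self._run(x[::-1], *self._dirs[1])[::-1]
        seq = [concat([f, bk], axis=1) for f, bk in zip(fwd, bwd)]
        return stack(seq, axis=0).reshape(len(seq), 2 * self.hidden)


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
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
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
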