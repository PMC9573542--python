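"""Compact numpy sequence classifiers: causal dilated 1-D convolutions
(TCN), LSTM, a plain 1-D conv net, and temporal+conv combinations.

These are small reference architectures for desk-scale experiments on
``[batch, channels, time]`` inputs (time = 8 for fine-grained feature
curves).  Training is full-precision Adam on softmax cross-entropy with an
internal validation split and early stopping; everything is seeded and
single-threaded, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer: owns parameter/gradient pairs."""

    def params(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1d(Layer):
    """Causal dilated 1-D convolution on (B, C, T); left zero padding keeps T."""

    def __init__(self, cin: int, cout: int, k: int, dilation: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k))
        self.W = rng.normal(0.0, scale, (cout, cin, k))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.d = k, dilation

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self.pad = (self.k - 1) * self.d
        self.xp = np.pad(x, ((0, 0), (0, 0), (self.pad, 0)))
        B, C, T = x.shape
        y = np.zeros((B, self.W.shape[0], T))
        for j in range(self.k):
            seg = self.xp[:, :, j * self.d : j * self.d + T]
            y += np.einsum("oc,bct->bot", self.W[:, :, j], seg)
        return y + self.b[None, :, None]

    def backward(self, dy):
        B, O, T = dy.shape
        dxp = np.zeros_like(self.xp)
        self.dW[...] = 0.0
        for j in range(self.k):
            seg = self.xp[:, :, j * self.d : j * self.d + T]
            self.dW[:, :, j] = np.einsum("bot,bct->oc", dy, seg)
            dxp[:, :, j * self.d : j * self.d + T] += np.einsum(
                "oc,bot->bct", self.W[:, :, j], dy
            )
        self.db[...] = dy.sum(axis=(0, 2))
        return dxp[:, :, self.pad :]


class ReLU(Layer):
    def forward(self, x):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask


class GlobalAvgPool(Layer):
    """(B, C, T) -> (B, C) mean over time."""

    def forward(self, x):
        self.T = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self.T, axis=2) / self.T


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, scale, (cin, cout))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self.x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class ResidualTCNBlock(Layer):
    """conv-relu-conv with a (possibly projected) skip connection."""

    def __init__(self, cin: int, cout: int, k: int, dilation: int, rng):
        self.c1 = Conv1d(cin, cout, k, dilation, rng)
        self.r1 = ReLU()
        self.c2 = Conv1d(cout, cout, k, dilation, rng)
        self.skip = Conv1d(cin, cout, 1, 1, rng) if cin != cout else None
        self.r2 = ReLU()

    def params(self):
        ps = self.c1.params() + self.c2.params()
        if self.skip is not None:
            ps += self.skip.params()
        return ps

    def forward(self, x):
        h = self.c2.forward(self.r1.forward(self.c1.forward(x)))
        s = self.skip.forward(x) if self.skip is not None else x
        return self.r2.forward(h + s)

    def backward(self, dy):
        dz = self.r2.backward(dy)
        dx = self.c1.backward(self.r1.backward(self.c2.backward(dz)))
        dx += self.skip.backward(dz) if self.skip is not None else dz
        return dx


class LSTMLayer(Layer):
    """Single-layer LSTM over (B, C, T); returns the last hidden state (B, H)."""

    def __init__(self, cin: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(max(cin, hidden))
        self.Wx = rng.normal(0.0, s, (cin, 4 * hidden))
        self.Wh = rng.normal(0.0, s, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        self.H = hidden

    def params(self):
        return [(self.Wx, self.dWx), (self.Wh, self.dWh), (self.b, self.db)]

    @staticmethod
    def _sigmoid(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))

    def forward(self, x):
        B, C, T = x.shape
        H = self.H
        self.x = x
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self.cache = []
        for t in range(T):
            xt = x[:, :, t]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self.cache.append((xt, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        return h

    def backward(self, dh_last):
        B, C, T = self.x.shape
        H = self.H
        self.dWx[...] = 0.0
        self.dWh[...] = 0.0
        self.db[...] = 0.0
        dx = np.zeros_like(self.x)
        dh = dh_last.copy()
        dc = np.zeros((B, H))
        for t in reversed(range(T)):
            xt, h_prev, c_prev, i, f, g, o, c_new = self.cache[t]
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g ** 2), do * o * (1 - o)],
                axis=1,
            )
            self.dWx += xt.T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, :, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


# ---------------------------------------------------------------------------
# architectures


class _SequenceNet:
    """A stack of layers ending in logits; input (B, C, T)."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def build_net(family: str, cin: int, n_classes: int, rng: np.random.Generator,
              width: int = 32, lstm_hidden: int = 64) -> _SequenceNet:
    """Reference architectures.

    ``cnn1d``: one causal conv + ReLU + global pooling + dense head.
    ``tcn``: three residual blocks with dilations 1/2/4, width 32.
    ``lstm``: single LSTM, hidden 64, last state + dense head.
    ``tcn_cnn`` / ``lstm_cnn``: the temporal trunk followed by an extra 1-D
    conv head before pooling (the "+ CNN" combinations).
    """
    if family == "cnn1d":
        layers = [Conv1d(cin, width, 3, 1, rng), ReLU(), GlobalAvgPool(),
                  Dense(width, n_classes, rng)]
    elif family == "tcn":
        layers = [ResidualTCNBlock(cin, width, 3, 1, rng),
                  ResidualTCNBlock(width, width, 3, 2, rng),
                  ResidualTCNBlock(width, width, 3, 4, rng),
                  GlobalAvgPool(), Dense(width, n_classes, rng)]
    elif family == "tcn_cnn":
        layers = [ResidualTCNBlock(cin, width, 3, 1, rng),
                  ResidualTCNBlock(width, width, 3, 2, rng),
                  Conv1d(width, width, 3, 1, rng), ReLU(),
                  GlobalAvgPool(), Dense(width, n_classes, rng)]
    elif family == "lstm":
        layers = [LSTMLayer(cin, lstm_hidden, rng), Dense(lstm_hidden, n_classes, rng)]
    elif family == "lstm_cnn":
        layers = [Conv1d(cin, width, 3, 1, rng), ReLU(),
                  LSTMLayer(width, lstm_hidden, rng), Dense(lstm_hidden, n_classes, rng)]
    else:
        raise ValueError(f"unknown neural family {family!r}")
    return _SequenceNet(layers)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    p = softmax(logits)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n


class Adam:
    def __init__(self, params, lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g ** 2
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-2
    val_fraction: float = 0.2
    patience: int = 10
    seed: int = 0


class SequenceClassifier:
    """Seeded trainer/predictor around a reference architecture.

    ``fit`` standardises channels with training statistics, trains with Adam
    and early-stops on an internal validation split; ``predict_proba``
    returns softmax scores.
    """

    def __init__(self, family: str, n_classes: int = 4,
                 train_config: Optional[TrainConfig] = None, **arch_kwargs):
        self.family = family
        self.n_classes = n_classes
        self.tc = train_config or TrainConfig()
        self.arch_kwargs = arch_kwargs
        self.net: Optional[_SequenceNet] = None

    def _standardize(self, X, fit=False):
        if fit:
            self.mu = X.mean(axis=(0, 2), keepdims=True)
            self.sd = X.std(axis=(0, 2), keepdims=True)
            self.sd[self.sd == 0] = 1.0
        return (X - self.mu) / self.sd

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SequenceClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError(f"expected [batch, channels, time] input, got shape {X.shape}")
        rng = np.random.default_rng(self.tc.seed)
        Xs = self._standardize(X, fit=True)
        n = len(y)
        order = rng.permutation(n)
        n_val = max(1, int(self.tc.val_fraction * n)) if n >= 10 else 0
        val_idx, tr_idx = order[:n_val], order[n_val:]
        self.net = build_net(self.family, X.shape[1], self.n_classes, rng,
                             **self.arch_kwargs)
        opt = Adam(self.net.params(), lr=self.tc.lr)
        best_val = np.inf
        best_state = [p.copy() for p, _ in self.net.params()]
        stale = 0
        for _epoch in range(self.tc.epochs):
            perm = rng.permutation(len(tr_idx))
            for start in range(0, len(tr_idx), self.tc.batch_size):
                idx = tr_idx[perm[start : start + self.tc.batch_size]]
                if len(idx) == 0:
                    continue
                logits = self.net.forward(Xs[idx])
                _loss, g = cross_entropy_grad(logits, y[idx])
                self.net.backward(g)
                opt.step()
            if n_val:
                logits = self.net.forward(Xs[val_idx])
                val_loss, _ = cross_entropy_grad(logits, y[val_idx])
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = [p.copy() for p, _ in self.net.params()]
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.tc.patience:
                        break
        if n_val:
            for (p, _), saved in zip(self.net.params(), best_state):
                p[...] = saved
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.net is None:
            raise RuntimeError("fit before predict")
        Xs = self._standardize(np.asarray(X, dtype=float))
        return softmax(self.net.forward(Xs))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def numerical_gradient_check(family: str = "tcn", seed: int = 0,
                             cin: int = 3, T: int = 8, n: int = 4,
                             eps: float = 1e-6) -> float:
    """Max relative error between backprop and central finite differences.

    All parameters are jittered to a generic point first: zero-initialised
    biases otherwise leave ReLU pre-activations exactly at the kink
    (wherever a receptive field sees only zeros), where the one-sided
    numerical derivative disagrees with the subgradient by construction.
    """
    rng = np.random.default_rng(seed)
    net = build_net(family, cin, 4, rng, width=5, lstm_hidden=5)
    for p, _ in net.params():
        p += rng.normal(0.0, 0.05, p.shape)
    X = rng.normal(size=(n, cin, T))
    y = rng.integers(0, 4, n)
    logits = net.forward(X)
    _, g = cross_entropy_grad(logits, y)
    net.backward(g)
    worst = 0.0
    for p, grad in net.params():
        flat = p.ravel()
        gflat = grad.ravel()
        idx = rng.choice(flat.size, size=min(5, flat.size), replace=False)
        for i in idx:
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = cross_entropy_grad(net.forward(X), y)
            flat[i] = orig - eps
            lm, _ = cross_entropy_grad(net.forward(X), y)
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(abs(num), abs(gflat[i]), 1e-8)
            worst = max(worst, abs(num - gflat[i]) / denom)
    return worst
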