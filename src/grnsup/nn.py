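"""Convolutional edge classifiers, implemented in NumPy with analytic gradients.

Two variants share the same building block: a width-1 "convolution" along the
pair axis (a dense 5 -> 16 -> 1 map applied to every pair row, with weights
shared across rows of the same role), each stage followed by batch
normalization and ReLU.  Separate kernel sets serve TF-gene rows and TF-TF
rows.

* Single-pair (SP): input ``(1 + n_tf) x 5`` -- one TF-gene row plus the fixed
  TF paired with every candidate TF.  The collapsed per-row map is fully
  connected to a 128-unit hidden layer and a single output logit.
* Multi-label (ML): input ``(n_tf + C(n_tf, 2)) x 5`` -- all TF-gene rows plus
  all unordered TF-TF pairs.  The concatenated maps connect to ``n_tf``
  output logits; connections from the TF-gene map carry dropout (rate 0.3)
  during training.

Batch normalization keeps running statistics (evaluation mode is exact for a
single sample) and carries learnable per-channel scale/shift; the trainable
parameter count is the closed form of the layer dimensions plus two affine
parameters per normalized channel.  Everything is float64; training is
deterministic given the seed.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import ConsistencyError, ParameterError

HIDDEN_SP = 128
CONV_CHANNELS = 16
ML_DROPOUT = 0.3


def sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(logits, labels, pos_weight: float = 1.0):
    """Mean weighted binary cross-entropy on logits, and its gradient.

    loss = mean( -[w * y * log sigma(z) + (1 - y) * log(1 - sigma(z))] ).
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(labels, dtype=float)
    softplus = np.logaddexp(0.0, z)  # -log(1 - sigma(z))
    softplus_neg = np.logaddexp(0.0, -z)  # -log sigma(z)
    loss = pos_weight * y * softplus_neg + (1.0 - y) * softplus
    s = sigmoid(z)
    grad = (s * (pos_weight * y + 1.0 - y) - pos_weight * y) / z.size
    return float(loss.mean()), grad


class BatchNorm:
    """Per-channel batch normalization with learnable scale and shift.

    Normalizes over all leading axes (batch and pair rows); channels last.
    The learnable shift matters structurally here: after the 16 -> 1 collapse
    a plain centered ReLU would clip roughly half of all pair rows to exactly
    zero, killing their gradients and tying their downstream scores; ``beta``
    lets the network move the activation distribution out of the dead zone.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.mean = np.zeros(channels)
        self.var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // x.shape[-1]
            self.mean = (1 - self.momentum) * self.mean + self.momentum * mu
            unbiased = var * n / max(n - 1, 1)
            self.var = (1 - self.momentum) * self.var + self.momentum * unbiased
        else:
            mu, var = self.mean, self.var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, axes, train)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray):
        """Returns ``(dx, dgamma, dbeta)``."""
        xhat, inv, axes, train = self._cache
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        if not train:
            return dxhat * inv, dgamma, dbeta
        m = dy.size // dy.shape[-1]
        dx = inv * (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes) / m)
        return dx, dgamma, dbeta

    def state(self) -> dict:
        return {
            "mean": self.mean.copy(), "var": self.var.copy(),
            "gamma": self.gamma.copy(), "beta": self.beta.copy(),
        }

    def load(self, st: dict) -> None:
        # in place: the parameter dict (and any optimizer) aliases gamma/beta
        self.mean[...] = st["mean"]
        self.var[...] = st["var"]
        self.gamma[...] = st["gamma"]
        self.beta[...] = st["beta"]


def _kaiming_uniform(rng, fan_in, shape):
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class _ConvStack:
    """Two (width-1 conv -> batchnorm -> ReLU) blocks: 5 -> 16 -> 1 channels."""

    def __init__(self, rng, prefix: str):
        self.prefix = prefix
        self.W1 = _kaiming_uniform(rng, 5, (5, CONV_CHANNELS))
        self.b1 = _kaiming_uniform(rng, 5, (CONV_CHANNELS,))
        self.W2 = _kaiming_uniform(rng, CONV_CHANNELS, (CONV_CHANNELS, 1))
        self.b2 = _kaiming_uniform(rng, CONV_CHANNELS, (1,))
        self.bn1 = BatchNorm(CONV_CHANNELS)
        self.bn2 = BatchNorm(1)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # x: (B, R, 5) -> (B, R) collapsed map
        z1 = x @ self.W1 + self.b1
        a1 = np.maximum(self.bn1.forward(z1, train), 0.0)
        z2 = a1 @ self.W2 + self.b2
        a2 = np.maximum(self.bn2.forward(z2, train), 0.0)
        self._cache = (x, z1, a1, z2, a2)
        return a2[..., 0]

    def backward(self, dmap: np.ndarray, grads: dict) -> np.ndarray:
        x, z1, a1, z2, a2 = self._cache
        da2 = dmap[..., None] * (a2 > 0)
        dz2, dg2, db2 = self.bn2.backward(da2)
        grads[self.prefix + "bn2_g"] = dg2
        grads[self.prefix + "bn2_b"] = db2
        grads[self.prefix + "W2"] = np.einsum("brc,brd->cd", a1, dz2)
        grads[self.prefix + "b2"] = dz2.sum(axis=(0, 1))
        da1 = (dz2 @ self.W2.T) * (a1 > 0)
        dz1, dg1, db1 = self.bn1.backward(da1)
        grads[self.prefix + "bn1_g"] = dg1
        grads[self.prefix + "bn1_b"] = db1
        grads[self.prefix + "W1"] = np.einsum("brc,brd->cd", x, dz1)
        grads[self.prefix + "b1"] = dz1.sum(axis=(0, 1))
        return dz1 @ self.W1.T

    def params(self) -> dict:
        p = self.prefix
        return {
            p + "W1": self.W1, p + "b1": self.b1, p + "W2": self.W2, p + "b2": self.b2,
            p + "bn1_g": self.bn1.gamma, p + "bn1_b": self.bn1.beta,
            p + "bn2_g": self.bn2.gamma, p + "bn2_b": self.bn2.beta,
        }

    def bn_state(self) -> dict:
        return {self.prefix + "bn1": self.bn1.state(), self.prefix + "bn2": self.bn2.state()}

    def load_bn(self, st: dict) -> None:
        self.bn1.load(st[self.prefix + "bn1"])
        self.bn2.load(st[self.prefix + "bn2"])


class _BaseNet:
    variant = ""

    def parameters(self) -> dict:
        raise NotImplementedError

    def n_parameters(self) -> int:
        return sum(v.size for v in self.parameters().values())

    def state_dict(self) -> dict:
        st = {k: v.copy() for k, v in self.parameters().items()}
        for stack in self._stacks():
            st.update({k: {kk: vv.copy() for kk, vv in s.items()} for k, s in stack.bn_state().items()})
        return st

    def load_state_dict(self, st: dict) -> None:
        for k, v in self.parameters().items():
            v[...] = st[k]
        for stack in self._stacks():
            stack.load_bn(st)


class SPNet(_BaseNet):
    """Single-pair classifier: one logit for "does this TF regulate this gene"."""

    variant = "sp"

    def __init__(self, n_tf: int, seed: int = 0):
        if n_tf < 1:
            raise ParameterError("n_tf must be >= 1")
        self.n_tf = n_tf
        self.n_pairs = 1 + n_tf
        rng = np.random.default_rng(seed)
        self.gene_stack = _ConvStack(rng, "g_")
        self.tf_stack = _ConvStack(rng, "t_")
        self.W3 = _kaiming_uniform(rng, self.n_pairs, (self.n_pairs, HIDDEN_SP))
        self.b3 = _kaiming_uniform(rng, self.n_pairs, (HIDDEN_SP,))
        self.W4 = _kaiming_uniform(rng, HIDDEN_SP, (HIDDEN_SP, 1))
        self.b4 = _kaiming_uniform(rng, HIDDEN_SP, (1,))
        self._cache = None

    def _stacks(self):
        return (self.gene_stack, self.tf_stack)

    def parameters(self) -> dict:
        p = {**self.gene_stack.params(), **self.tf_stack.params()}
        p.update({"W3": self.W3, "b3": self.b3, "W4": self.W4, "b4": self.b4})
        return p

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """X: (B, 1 + n_tf, 5), TF-gene row first.  Returns (B,) logits."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (self.n_pairs, 5):
            raise ConsistencyError(f"expected (B, {self.n_pairs}, 5) input, got {X.shape}")
        g = self.gene_stack.forward(X[:, :1, :], train)  # (B, 1)
        t = self.tf_stack.forward(X[:, 1:, :], train)  # (B, n_tf)
        f = np.concatenate([g, t], axis=1)
        h = np.maximum(f @ self.W3 + self.b3, 0.0)
        z = h @ self.W4 + self.b4
        self._cache = (f, h)
        return z[:, 0]

    def backward(self, dlogits: np.ndarray) -> dict:
        f, h = self._cache
        grads: dict = {}
        dz = np.asarray(dlogits)[:, None]
        grads["W4"] = h.T @ dz
        grads["b4"] = dz.sum(axis=0)
        dh = (dz @ self.W4.T) * (h > 0)
        grads["W3"] = f.T @ dh
        grads["b3"] = dh.sum(axis=0)
        df = dh @ self.W3.T
        self.gene_stack.backward(df[:, :1], grads)
        self.tf_stack.backward(df[:, 1:], grads)
        return grads


class MLNet(_BaseNet):
    """Multi-label classifier: n_tf logits, one per candidate TF, in one pass."""

    variant = "ml"

    def __init__(self, n_tf: int, seed: int = 0, dropout: float = ML_DROPOUT):
        if n_tf < 2:
            raise ParameterError("n_tf must be >= 2 for the multi-label variant")
        self.n_tf = n_tf
        self.n_tf_tf = n_tf * (n_tf - 1) // 2
        self.n_pairs = n_tf + self.n_tf_tf
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        self.gene_stack = _ConvStack(rng, "g_")
        self.tf_stack = _ConvStack(rng, "t_")
        self.Wout = _kaiming_uniform(rng, self.n_pairs, (self.n_pairs, n_tf))
        self.bout = _kaiming_uniform(rng, self.n_pairs, (n_tf,))
        self._cache = None
        self._rng = np.random.default_rng(seed + 1)

    def _stacks(self):
        return (self.gene_stack, self.tf_stack)

    def parameters(self) -> dict:
        p = {**self.gene_stack.params(), **self.tf_stack.params()}
        p.update({"Wout": self.Wout, "bout": self.bout})
        return p

    def forward(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        """X: (B, n_tf + C(n_tf, 2), 5), TF-gene rows first.  Returns (B, n_tf) logits."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.shape[1:] != (self.n_pairs, 5):
            raise ConsistencyError(f"expected (B, {self.n_pairs}, 5) input, got {X.shape}")
        g = self.gene_stack.forward(X[:, : self.n_tf, :], train)  # (B, n_tf)
        t = self.tf_stack.forward(X[:, self.n_tf:, :], train)  # (B, C(n_tf,2))
        if train and self.dropout > 0:
            if self.dropout >= 1.0:
                g = np.zeros_like(g)
                mask = np.zeros_like(g)
            else:
                mask = (self._rng.random(g.shape) >= self.dropout) / (1.0 - self.dropout)
                g = g * mask
        else:
            mask = None
        f = np.concatenate([g, t], axis=1)
        z = f @ self.Wout + self.bout
        self._cache = (f, mask)
        return z

    def backward(self, dlogits: np.ndarray) -> dict:
        f, mask = self._cache
        grads: dict = {}
        dz = np.asarray(dlogits)
        grads["Wout"] = f.T @ dz
        grads["bout"] = dz.sum(axis=0)
        df = dz @ self.Wout.T
        dg = df[:, : self.n_tf]
        if mask is not None:
            dg = dg * mask
        self.gene_stack.backward(dg, grads)
        self.tf_stack.backward(df[:, self.n_tf:], grads)
        return grads


class Adam:
    """Adam with (coupled) L2 weight decay added to the gradient."""

    def __init__(self, params: dict, lr: float = 2e-4, weight_decay: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k].reshape(p.shape) + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
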