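"""Minimal dense neural networks with hand-written backpropagation.

Four-layer densely connected networks map a conformation vector to decoder
outputs (patch transforms, residue transforms, per-atom offsets).  The
final layer is zero-initialized so an untrained decoder emits exactly zero
-- the refined model then equals the input model bit-for-bit before
training.  Optimization uses Adam.
"""

from __future__ import annotations

import numpy as np


class MLP:
    """Fully connected ReLU network; last layer linear and zero-initialized."""

    def __init__(self, in_dim: int, out_dim: int, width: int = 64,
                 depth: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [in_dim] + [width] * (depth - 1) + [out_dim]
        self.W, self.b = [], []
        for i in range(depth):
            if i == depth - 1:
                w = np.zeros((dims[i], dims[i + 1]))
            else:
                w = rng.normal(scale=np.sqrt(2.0 / dims[i]),
                               size=(dims[i], dims[i + 1]))
            self.W.append(w)
            self.b.append(np.zeros(dims[i + 1]))
        self._cache = None

    @property
    def params(self):
        return self.W + self.b

    def reinitialize(self, seed: int = 0) -> None:
        fresh = MLP(self.W[0].shape[0], self.W[-1].shape[1],
                    self.W[0].shape[1] if len(self.W) > 1
                    else self.W[0].shape[1], len(self.W), seed)
        self.W, self.b = fresh.W, fresh.b
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        acts = [x]
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            x = x @ w + b
            if i < len(self.W) - 1:
                x = np.maximum(x, 0.0)
            acts.append(x)
        self._cache = acts
        return x

    def backward(self, dy: np.ndarray):
        """Gradients of all parameters given d(loss)/d(output); returns
        them in the order of ``params``."""
        acts = self._cache
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        g = np.atleast_2d(dy)
        for i in range(len(self.W) - 1, -1, -1):
            if i < len(self.W) - 1:
                g = g * (acts[i + 1] > 0)
            dW[i] = acts[i].T @ g
            db[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return dW + db


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def euler_zyx_with_grad(angles):
    """Rotation Rz(a)Ry(b)Rx(c) and its three angle derivatives."""
    a, b, c = angles
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    Rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
    dRz = np.array([[-sa, -ca, 0], [ca, -sa, 0], [0, 0, 0]])
    dRy = np.array([[-sb, 0, cb], [0, 0, 0], [-cb, 0, -sb]])
    dRx = np.array([[0, 0, 0], [0, -sc, -cc], [0, cc, -sc]])
    R = Rz @ Ry @ Rx
    return R, (dRz @ Ry @ Rx, Rz @ dRy @ Rx, Rz @ Ry @ dRx)
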