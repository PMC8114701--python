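"""Minimal numpy neural-network core: BiLSTM and CNN with backprop.

Implements exactly the two architectures the classifiers need, at desk
scale on one CPU:

* :class:`BiLstmNet` — word embedding (padding token 0 masked, zero
  embedding) -> bidirectional LSTM -> dropout -> dense sigmoid scalar;
  binary cross-entropy loss.
* :class:`ConvNet` — two valid 1-D convolutions over the one-hot columns
  (the first kernel spans all four base rows, so a 4xK then 1xK 2-D view
  is equivalent), each followed by ReLU and max-pooling, then dropout and
  a 2-way softmax dense layer; categorical cross-entropy loss.

Parameters live in a ``params`` dict (name -> ndarray) consumed by the
:class:`Adam` and :class:`SGD` optimizers.  All randomness (init, batch
shuffling, dropout masks) flows through a single ``numpy`` Generator, so
training is bitwise reproducible single-threaded.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# optimizers


class Adam:
    """Adam with the customary defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999):
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / (1 - self.beta1**self.t)
            vhat = self.v[name] / (1 - self.beta2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


class SGD:
    """Stochastic gradient descent with optional momentum."""

    def __init__(self, lr: float = 0.01, momentum: float = 0.0):
        self.lr, self.momentum = lr, momentum
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict, grads: dict) -> None:
        for name, g in grads.items():
            if self.momentum:
                v = self.v.get(name)
                v = g if v is None else self.momentum * v + g
                self.v[name] = v
                params[name] -= self.lr * v
            else:
                params[name] -= self.lr * g


# ---------------------------------------------------------------------------
# BiLSTM


class BiLstmNet:
    """Embedding -> bidirectional LSTM -> dropout -> sigmoid unit."""

    def __init__(
        self,
        vocab_size: int,
        embed_dim: int,
        units: int,
        dropout: float = 0.4,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.vocab_size = vocab_size
        self.embed_dim = embed_dim
        self.units = units
        self.dropout = dropout
        d, u = embed_dim, units
        p: dict[str, np.ndarray] = {}
        p["E"] = rng.normal(0.0, 0.1, size=(vocab_size, d))
        p["E"][0] = 0.0  # padding embedding stays zero
        for dr in ("f", "b"):
            p[f"Wx_{dr}"] = rng.normal(0.0, 1.0 / np.sqrt(d), size=(d, 4 * u))
            p[f"Wh_{dr}"] = rng.normal(0.0, 1.0 / np.sqrt(u), size=(u, 4 * u))
            bias = np.zeros(4 * u)
            bias[u : 2 * u] = 1.0  # forget-gate bias
            p[f"b_{dr}"] = bias
        p["Wout"] = rng.normal(0.0, 0.05, size=(2 * u,))
        p["bout"] = np.zeros(1)
        self.params = p

    # -- forward -----------------------------------------------------------

    def _run_direction(self, x, mask, direction):
        """Run one LSTM direction; returns final h and per-step caches."""
        p = self.params
        Wx, Wh, b = p[f"Wx_{direction}"], p[f"Wh_{direction}"], p[f"b_{direction}"]
        B, T, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        order = range(T) if direction == "f" else range(T - 1, -1, -1)
        steps = []
        for t in order:
            z = x[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t : t + 1]
            steps.append((t, i, f, g, o, c, h, tc, m))
            h = m * h_new + (1 - m) * h
            c = m * c_new + (1 - m) * c
        return h, steps

    def forward(self, tokens, train=False, rng=None):
        """Confidence probabilities for a batch of token vectors (B, T)."""
        p = self.params
        mask = (tokens > 0).astype(float)
        x = p["E"][tokens]  # (B, T, d)
        hf, steps_f = self._run_direction(x, mask, "f")
        hb, steps_b = self._run_direction(x, mask, "b")
        feat = np.concatenate([hf, hb], axis=1)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            dmask = (rng.random(feat.shape) < keep) / keep
            feat_d = feat * dmask
        else:
            dmask = None
            feat_d = feat
        logit = feat_d @ p["Wout"] + p["bout"][0]
        cp = _sigmoid(logit)
        cache = (tokens, mask, x, steps_f, steps_b, feat, dmask, feat_d)
        return cp, cache

    # -- backward ----------------------------------------------------------

    def _back_direction(self, x, steps, dh_final, direction, grads, dx):
        p = self.params
        Wx, Wh = p[f"Wx_{direction}"], p[f"Wh_{direction}"]
        u = self.units
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * u)
        dh = dh_final
        dc = np.zeros_like(dh_final)
        for (t, i, f, g, o, c_prev, h_prev, tc, m) in reversed(steps):
            dh_new = m * dh
            dc_new = m * dc
            dh_carry = (1 - m) * dh
            dc_carry = (1 - m) * dc
            do = dh_new * tc
            dct = dc_new + dh_new * o * (1 - tc * tc)
            di = dct * g
            df = dct * c_prev
            dg = dct * i
            dc = dct * f + dc_carry
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] += dz @ Wx.T
            dh = dz @ Wh.T + dh_carry
        grads[f"Wx_{direction}"] = dWx
        grads[f"Wh_{direction}"] = dWh
        grads[f"b_{direction}"] = db

    def loss_and_grads(self, tokens, y, rng=None):
        """Mean binary cross-entropy and parameter gradients for a batch."""
        cp, cache = self.forward(tokens, train=True, rng=rng)
        tokens_, mask, x, steps_f, steps_b, feat, dmask, feat_d = cache
        B = len(y)
        loss = -np.mean(y * np.log(cp + _EPS) + (1 - y) * np.log(1 - cp + _EPS))
        dlogit = (cp - y) / B
        grads: dict[str, np.ndarray] = {}
        grads["Wout"] = feat_d.T @ dlogit
        grads["bout"] = np.array([dlogit.sum()])
        dfeat = np.outer(dlogit, self.params["Wout"])
        if dmask is not None:
            dfeat = dfeat * dmask
        u = self.units
        dx = np.zeros_like(x)
        self._back_direction(x, steps_f, dfeat[:, :u], "f", grads, dx)
        self._back_direction(x, steps_b, dfeat[:, u:], "b", grads, dx)
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, tokens_.reshape(-1), dx.reshape(-1, x.shape[-1]))
        dE[0] = 0.0  # padding embedding is frozen
        grads["E"] = dE
        return loss, grads

    def predict(self, tokens, batch_size: int = 256) -> np.ndarray:
        out = []
        for s in range(0, len(tokens), batch_size):
            cp, _ = self.forward(tokens[s : s + batch_size], train=False)
            out.append(cp)
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# CNN


class ConvNet:
    """conv(F1) -> maxpool -> conv(F2) -> maxpool -> dropout -> softmax(2)."""

    def __init__(
        self,
        n_columns: int,
        filters: tuple[int, int] = (32, 64),
        kernel: int = 8,
        pool: int = 2,
        dropout: float = 0.4,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.n_columns = n_columns
        self.filters = filters
        self.kernel = kernel
        self.pool = pool
        self.dropout = dropout
        F1, F2 = filters
        o1 = n_columns - kernel + 1
        p1 = o1 // pool
        o2 = p1 - kernel + 1
        p2 = o2 // pool
        if o1 < 1 or o2 < 1 or p2 < 1:
            min_n = self._min_columns(kernel, pool)
            raise ValueError(
                f"input width {n_columns} smaller than the receptive field; "
                f"need at least {min_n} columns for kernel {kernel}, pool {pool}"
            )
        self.p2 = p2
        p: dict[str, np.ndarray] = {}
        p["W1"] = rng.normal(0.0, np.sqrt(2.0 / (kernel * 4)), size=(kernel, 4, F1))
        p["b1"] = np.zeros(F1)
        p["W2"] = rng.normal(0.0, np.sqrt(2.0 / (kernel * F1)), size=(kernel, F1, F2))
        p["b2"] = np.zeros(F2)
        p["Wd"] = rng.normal(0.0, np.sqrt(1.0 / (p2 * F2)), size=(p2 * F2, 2))
        p["bd"] = np.zeros(2)
        self.params = p

    @staticmethod
    def _min_columns(kernel: int, pool: int) -> int:
        # smallest N with (((N-k+1)//pool) - k + 1) // pool >= 1
        n = kernel
        while ((((n - kernel + 1) // pool) - kernel + 1)) < pool:
            n += 1
        return n

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    @staticmethod
    def _conv(x, W, b):
        k = W.shape[0]
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B,O,C,k)
        out = np.einsum("bock,kcf->bof", cols, W) + b
        return out, cols

    @staticmethod
    def _conv_back(cols, W, dout, x_shape):
        k = W.shape[0]
        dW = np.einsum("bock,bof->kcf", cols, dout)
        db = dout.sum(axis=(0, 1))
        dx = np.zeros(x_shape)
        O = dout.shape[1]
        for off in range(k):
            dx[:, off : off + O, :] += dout @ W[off].T
        return dW, db, dx

    def _pool(self, x):
        B, O, F = x.shape
        P = O // self.pool
        y = x[:, : P * self.pool].reshape(B, P, self.pool, F)
        arg = y.argmax(axis=2)
        out = np.take_along_axis(y, arg[:, :, None, :], axis=2)[:, :, 0, :]
        return out, (arg, x.shape)

    def _pool_back(self, dout, cache):
        arg, x_shape = cache
        B, O, F = x_shape
        P = O // self.pool
        dy = np.zeros((B, P, self.pool, F))
        np.put_along_axis(dy, arg[:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros(x_shape)
        dx[:, : P * self.pool] = dy.reshape(B, P * self.pool, F)
        return dx

    def forward(self, X, train=False, rng=None):
        """Class probabilities (B, 2) for one-hot batches (B, 4, N)."""
        p = self.params
        x = np.ascontiguousarray(np.transpose(X, (0, 2, 1)), dtype=float)  # (B,N,4)
        z1, cols1 = self._conv(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        q1, pc1 = self._pool(a1)
        z2, cols2 = self._conv(q1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        q2, pc2 = self._pool(a2)
        flat = q2.reshape(len(X), -1)
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            dmask = (rng.random(flat.shape) < keep) / keep
            flat_d = flat * dmask
        else:
            dmask = None
            flat_d = flat
        logits = flat_d @ p["Wd"] + p["bd"]
        probs = _softmax(logits)
        cache = (x, cols1, z1, pc1, q1, cols2, z2, pc2, q2, flat, dmask, flat_d)
        return probs, cache

    def loss_and_grads(self, X, y_onehot, rng=None):
        """Mean categorical cross-entropy and gradients for a batch."""
        probs, cache = self.forward(X, train=True, rng=rng)
        x, cols1, z1, pc1, q1, cols2, z2, pc2, q2, flat, dmask, flat_d = cache
        p = self.params
        B = len(X)
        loss = -np.mean(np.sum(y_onehot * np.log(probs + _EPS), axis=1))
        dlogits = (probs - y_onehot) / B
        grads: dict[str, np.ndarray] = {}
        grads["Wd"] = flat_d.T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["Wd"].T
        if dmask is not None:
            dflat = dflat * dmask
        dq2 = dflat.reshape(q2.shape)
        da2 = self._pool_back(dq2, pc2)
        dz2 = da2 * (z2 > 0)
        grads["W2"], grads["b2"], dq1 = self._conv_back(cols2, p["W2"], dz2, q1.shape)
        da1 = self._pool_back(dq1, pc1)
        dz1 = da1 * (z1 > 0)
        grads["W1"], grads["b1"], _ = self._conv_back(cols1, p["W1"], dz1, x.shape)
        return loss, grads

    def predict(self, X, batch_size: int = 256) -> np.ndarray:
        out = []
        for s in range(0, len(X), batch_size):
            probs, _ = self.forward(X[s : s + batch_size], train=False)
            out.append(probs)
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# shared training loop


def clip_by_global_norm(grads: dict, max_norm: float) -> None:
    """Rescale all gradients in place if their global norm exceeds max_norm."""
    norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
    if norm > max_norm:
        scale = max_norm / norm
        for g in grads.values():
            g *= scale


def train_network(
    net,
    X: np.ndarray,
    y: np.ndarray,
    optimizer,
    epochs: int,
    batch_size: int,
    rng: np.random.Generator,
    clipnorm: float | None = None,
) -> list[float]:
    """Mini-batch training; returns the mean loss per epoch."""
    n = len(X)
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for s in range(0, n, batch_size):
            idx = order[s : s + batch_size]
            loss, grads = net.loss_and_grads(X[idx], y[idx], rng=rng)
            if clipnorm is not None:
                clip_by_global_norm(grads, clipnorm)
            optimizer.step(net.params, grads)
            total += loss * len(idx)
        history.append(total / n)
    return history
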