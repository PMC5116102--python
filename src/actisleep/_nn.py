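"""Numpy building blocks for the sleep-quality classifiers.

Implements forward/backward passes for the six architectures (logistic
regression, MLP, 1-d CNN, Elman RNN with ReLU units, LSTM, and the
time-batched LSTM), an RMSprop optimizer, inverted dropout, and a training
loop that minimizes binary cross-entropy with early stopping on validation
accuracy.

Everything is deterministic given a :class:`numpy.random.Generator`; dropout
masks, weight init and mini-batch shuffling all draw from the one stream.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

Params = dict[str, np.ndarray]

EPS = 1e-12


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _dropout_mask(rng: np.random.Generator, shape, ratio: float) -> np.ndarray:
    """Inverted dropout mask: zeros a `ratio` fraction, rescales the rest."""
    if ratio <= 0.0:
        return np.ones(shape)
    keep = 1.0 - ratio
    return (rng.random(shape) < keep) / keep


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    scale = math.sqrt(2.0 / (n_in + n_out))
    return rng.normal(0.0, scale, size=(n_in, n_out))


class _Network:
    """Interface: init_params / forward (returns probs + cache) / backward."""

    dropout: float = 0.0

    def init_params(self, rng: np.random.Generator) -> Params:
        raise NotImplementedError

    def forward(self, params: Params, batch, train: bool, rng) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def backward(self, params: Params, cache: dict, dz: np.ndarray) -> Params:
        raise NotImplementedError


class LogisticNet(_Network):
    """Raw input fed directly to a single sigmoid output unit.

    Having no hidden layer, the dropout ratio is applied to the input vector.
    """

    def __init__(self, n_features: int, dropout: float = 0.5):
        self.n_features = n_features
        self.dropout = dropout

    def init_params(self, rng):
        return {"w": _glorot(rng, self.n_features, 1), "b": np.zeros(1)}

    def forward(self, params, X, train, rng):
        Xd = X * _dropout_mask(rng, X.shape, self.dropout) if train else X
        z = Xd @ params["w"] + params["b"]
        return sigmoid(z)[:, 0], {"Xd": Xd}

    def backward(self, params, cache, dz):
        return {"w": cache["Xd"].T @ dz[:, None], "b": dz.sum(keepdims=True)}


class MLPNet(_Network):
    """One fully connected ReLU hidden layer, then a sigmoid output.

    With ``hidden_size=0`` the input feeds the output unit directly — the
    degenerate MLP that coincides with logistic regression.
    """

    def __init__(self, n_features: int, hidden_size: int = 15, dropout: float = 0.1):
        self.n_features = n_features
        self.hidden_size = hidden_size
        self.dropout = dropout

    def init_params(self, rng):
        if self.hidden_size == 0:
            return {"w2": _glorot(rng, self.n_features, 1), "b2": np.zeros(1)}
        return {
            "W1": _glorot(rng, self.n_features, self.hidden_size),
            "b1": np.zeros(self.hidden_size),
            "w2": _glorot(rng, self.hidden_size, 1),
            "b2": np.zeros(1),
        }

    def forward(self, params, X, train, rng):
        if self.hidden_size == 0:
            Xd = X * _dropout_mask(rng, X.shape, self.dropout) if train else X
            z = Xd @ params["w2"] + params["b2"]
            return sigmoid(z)[:, 0], {"hd": Xd}
        a = X @ params["W1"] + params["b1"]
        h = np.maximum(a, 0.0)
        dmask = _dropout_mask(rng, h.shape, self.dropout) if train else 1.0
        hd = h * dmask
        z = hd @ params["w2"] + params["b2"]
        return sigmoid(z)[:, 0], {"X": X, "a": a, "hd": hd, "dmask": dmask}

    def backward(self, params, cache, dz):
        if self.hidden_size == 0:
            dz = dz[:, None]
            return {"w2": cache["hd"].T @ dz, "b2": dz.sum(axis=0)}
        dz = dz[:, None]
        dh = (dz @ params["w2"].T) * cache["dmask"]
        da = dh * (cache["a"] > 0)
        return {
            "w2": cache["hd"].T @ dz,
            "b2": dz.sum(axis=0),
            "W1": cache["X"].T @ da,
            "b1": da.sum(axis=0),
        }


class ConvNet(_Network):
    """One 1-d convolution (ReLU) + max-pooling + sigmoid output.

    Minimal convolutional topology: ``n_filters`` kernels of ``filter_length``
    slide over the minute series (valid convolution), non-overlapping
    max-pooling of ``pool_length`` picks the most significant local features,
    and the flattened map feeds the output unit.
    """

    def __init__(
        self,
        n_features: int,
        n_filters: int = 25,
        filter_length: int = 5,
        pool_length: int = 4,
        dropout: float = 0.0,
    ):
        self.n_features = n_features
        self.n_filters = n_filters
        self.filter_length = filter_length
        self.pool_length = pool_length
        self.dropout = dropout
        self.conv_len = n_features - filter_length + 1
        if self.conv_len < pool_length:
            raise ValueError("input shorter than one pooling window")
        self.pooled_len = self.conv_len // pool_length
        self.flat_len = self.pooled_len * n_filters

    def init_params(self, rng):
        return {
            "F": _glorot(rng, self.filter_length, self.n_filters),
            "bf": np.zeros(self.n_filters),
            "w": _glorot(rng, self.flat_len, 1),
            "b": np.zeros(1),
        }

    def forward(self, params, X, train, rng):
        Xw = np.lib.stride_tricks.sliding_window_view(X, self.filter_length, axis=1)
        a = Xw @ params["F"] + params["bf"]  # (B, conv_len, n_filters)
        h = np.maximum(a, 0.0)
        k = self.pooled_len * self.pool_length
        blocks = h[:, :k].reshape(len(X), self.pooled_len, self.pool_length, self.n_filters)
        argmax = blocks.argmax(axis=2)
        pooled = np.take_along_axis(blocks, argmax[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(len(X), self.flat_len)
        dmask = _dropout_mask(rng, flat.shape, self.dropout) if train else 1.0
        fd = flat * dmask
        z = fd @ params["w"] + params["b"]
        return sigmoid(z)[:, 0], {"Xw": Xw, "a": a, "argmax": argmax, "fd": fd, "dmask": dmask}

    def backward(self, params, cache, dz):
        dz = dz[:, None]
        B = len(dz)
        dflat = (dz @ params["w"].T) * cache["dmask"]
        dpooled = dflat.reshape(B, self.pooled_len, self.n_filters)
        dblocks = np.zeros((B, self.pooled_len, self.pool_length, self.n_filters))
        np.put_along_axis(dblocks, cache["argmax"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        dh = np.zeros_like(cache["a"])
        k = self.pooled_len * self.pool_length
        dh[:, :k] = dblocks.reshape(B, k, self.n_filters)
        da = dh * (cache["a"] > 0)
        return {
            "w": cache["fd"].T @ dz,
            "b": dz.sum(axis=0),
            "F": np.einsum("btk,btf->kf", cache["Xw"], da),
            "bf": da.sum(axis=(0, 1)),
        }


class _RecurrentNet(_Network):
    """Shared masking/output logic for the Elman RNN and the LSTMs.

    Sequences arrive left-padded as ``(X, mask)`` with shapes ``(B, T, D)``
    and ``(B, T)``; masked steps carry the hidden (and cell) state through
    unchanged. The final hidden state, after dropout, feeds the output unit.
    """

    hidden_size: int

    def _out_forward(self, params, hT, train, rng):
        dmask = _dropout_mask(rng, hT.shape, self.dropout) if train else 1.0
        hd = hT * dmask
        z = hd @ params["w"] + params["b"]
        return sigmoid(z)[:, 0], (hd, dmask)

    def _out_backward(self, params, out_cache, dz):
        hd, dmask = out_cache
        dz = dz[:, None]
        dh = (dz @ params["w"].T) * dmask
        return {"w": hd.T @ dz, "b": dz.sum(axis=0)}, dh


class ElmanNet(_RecurrentNet):
    """Simple recurrent network with rectified-linear hidden units.

    The recurrent matrix is initialized at (near) identity — with ReLU units
    this keeps gradients usable over minute-resolution sequences, where a
    small random recurrent init would vanish within tens of steps.
    """

    def __init__(self, n_inputs: int, hidden_size: int = 75, dropout: float = 0.1):
        self.n_inputs = n_inputs
        self.hidden_size = hidden_size
        self.dropout = dropout

    def init_params(self, rng):
        H = self.hidden_size
        return {
            "Wx": _glorot(rng, self.n_inputs, H),
            "Wh": np.eye(H) + rng.normal(0.0, 0.001, size=(H, H)),
            "bh": np.zeros(H),
            "w": _glorot(rng, H, 1),
            "b": np.zeros(1),
        }

    def forward(self, params, batch, train, rng):
        X, mask = batch
        B, T, _ = X.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        Hs = np.empty((B, T, H))
        As = np.empty((B, T, H))
        for t in range(T):
            a = X[:, t] @ params["Wx"] + h @ params["Wh"] + params["bh"]
            m = mask[:, t : t + 1]
            h = np.where(m, np.maximum(a, 0.0), h)
            As[:, t] = a
            Hs[:, t] = h
        p, hd = self._out_forward(params, h, train, rng)
        return p, {"X": X, "mask": mask, "As": As, "Hs": Hs, "hd": hd}

    def backward(self, params, cache, dz):
        X, mask, As, Hs = cache["X"], cache["mask"], cache["As"], cache["Hs"]
        B, T, _ = X.shape
        grads, dh = self._out_backward(params, cache["hd"], dz)
        grads["Wx"] = np.zeros_like(params["Wx"])
        grads["Wh"] = np.zeros_like(params["Wh"])
        grads["bh"] = np.zeros_like(params["bh"])
        for t in range(T - 1, -1, -1):
            m = mask[:, t : t + 1]
            da = dh * (As[:, t] > 0) * m
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros_like(dh)
            grads["Wx"] += X[:, t].T @ da
            grads["Wh"] += h_prev.T @ da
            grads["bh"] += da.sum(axis=0)
            dh = da @ params["Wh"].T + dh * (~m)
        return grads


class LSTMNet(_RecurrentNet):
    """LSTM with standard memory blocks (sigmoid gates, tanh cell).

    With ``n_inputs > 1`` this is the time-batched variant: each step consumes
    a merged window of consecutive activity minutes, shortening the sequence.
    """

    def __init__(self, n_inputs: int, hidden_size: int = 100, dropout: float = 0.5):
        self.n_inputs = n_inputs
        self.hidden_size = hidden_size
        self.dropout = dropout

    def init_params(self, rng):
        H = self.hidden_size
        params = {
            "Wx": _glorot(rng, self.n_inputs, 4 * H),
            "Wh": _glorot(rng, H, 4 * H),
            "bg": np.zeros(4 * H),
            "w": _glorot(rng, H, 1),
            "b": np.zeros(1),
        }
        params["bg"][H : 2 * H] = 1.0  # forget-gate bias: remember by default
        return params

    def forward(self, params, batch, train, rng):
        X, mask = batch
        B, T, _ = X.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        gates = np.empty((B, T, 4 * H))
        Cs = np.empty((B, T, H))
        Hs = np.empty((B, T, H))
        for t in range(T):
            a = X[:, t] @ params["Wx"] + h @ params["Wh"] + params["bg"]
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            m = mask[:, t : t + 1]
            h = np.where(m, h_new, h)
            c = np.where(m, c_new, c)
            gates[:, t] = np.concatenate([i, f, g, o], axis=1)
            Cs[:, t] = c
            Hs[:, t] = h
        p, hd = self._out_forward(params, h, train, rng)
        return p, {"X": X, "mask": mask, "gates": gates, "Cs": Cs, "Hs": Hs, "hd": hd}

    def backward(self, params, cache, dz):
        X, mask = cache["X"], cache["mask"]
        gates, Cs, Hs = cache["gates"], cache["Cs"], cache["Hs"]
        B, T, _ = X.shape
        H = self.hidden_size
        grads, dh = self._out_backward(params, cache["hd"], dz)
        grads["Wx"] = np.zeros_like(params["Wx"])
        grads["Wh"] = np.zeros_like(params["Wh"])
        grads["bg"] = np.zeros_like(params["bg"])
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            m = mask[:, t : t + 1]
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            c_prev = Cs[:, t - 1] if t > 0 else np.zeros((B, H))
            h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, H))
            tanh_c = np.tanh(Cs[:, t])
            dh_eff = dh * m
            dc_eff = dc * m + dh_eff * o * (1.0 - tanh_c**2)
            da = np.concatenate(
                [
                    dc_eff * g * i * (1.0 - i),
                    dc_eff * c_prev * f * (1.0 - f),
                    dc_eff * i * (1.0 - g**2),
                    dh_eff * tanh_c * o * (1.0 - o),
                ],
                axis=1,
            )
            grads["Wx"] += X[:, t].T @ da
            grads["Wh"] += h_prev.T @ da
            grads["bg"] += da.sum(axis=0)
            dh = da @ params["Wh"].T + dh * (~m)
            dc = dc_eff * f + dc * (~m)
        return grads


class RMSprop:
    """RMSprop: per-parameter adaptive step from a running mean of squared grads."""

    def __init__(self, learning_rate: float = 0.001, rho: float = 0.9, eps: float = 1e-8):
        self.learning_rate = learning_rate
        self.rho = rho
        self.eps = eps
        self._v: Params = {}

    def step(self, params: Params, grads: Params) -> None:
        for name, g in grads.items():
            v = self._v.get(name)
            if v is None:
                v = np.zeros_like(g)
            v = self.rho * v + (1.0 - self.rho) * g * g
            self._v[name] = v
            params[name] -= self.learning_rate * g / (np.sqrt(v) + self.eps)


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


def _batch_slice(batch, idx):
    if isinstance(batch, tuple):
        return tuple(part[idx] for part in batch)
    return batch[idx]


def _batch_len(batch) -> int:
    return len(batch[0]) if isinstance(batch, tuple) else len(batch)


def train_network(
    net: _Network,
    params: Params,
    train_batch,
    y_train: np.ndarray,
    val_batch,
    y_val: np.ndarray,
    *,
    mini_batch_size: int,
    max_epochs: int,
    learning_rate: float,
    rng: np.random.Generator,
    clip_norm: float = 5.0,
    callback: Callable[[dict], None] | None = None,
) -> tuple[Params, list[dict]]:
    """Mini-batch RMSprop on binary cross-entropy with early stopping.

    After every epoch the model is evaluated on the validation set; training
    stops at the first epoch whose validation accuracy falls below the
    previous epoch's, restoring the previous epoch's parameters (equal
    accuracy continues training). At most ``max_epochs`` epochs run.
    Gradients are clipped to a global norm of ``clip_norm`` — exploding
    back-propagated-through-time gradients would otherwise derail the
    recurrent models on minute-resolution sequences.
    """
    opt = RMSprop(learning_rate=learning_rate)
    n = _batch_len(train_batch)
    log: list[dict] = []
    prev_acc = -np.inf
    prev_params: Params = {k: v.copy() for k, v in params.items()}
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, mini_batch_size):
            idx = order[start : start + mini_batch_size]
            xb = _batch_slice(train_batch, idx)
            yb = y_train[idx]
            p, cache = net.forward(params, xb, train=True, rng=rng)
            loss = bce_loss(p, yb)
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)
            dz = (np.clip(p, EPS, 1 - EPS) - yb) / len(yb)
            grads = net.backward(params, cache, dz)
            if clip_norm is not None:
                total = math.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                if total > clip_norm:
                    grads = {k: g * (clip_norm / total) for k, g in grads.items()}
            opt.step(params, grads)
            losses.append(loss)
        p_val, _ = net.forward(params, val_batch, train=False, rng=rng)
        val_acc = float(np.mean((p_val >= 0.5) == (y_val == 1)))
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_accuracy": val_acc,
        }
        log.append(entry)
        if callback is not None:
            callback(entry)
        if val_acc < prev_acc:
            params = prev_params
            entry["early_stopped"] = True
            break
        prev_acc = val_acc
        prev_params = {k: v.copy() for k, v in params.items()}
    return params, log


def numerical_gradient(loss_fn: Callable[[Params], float], params: Params, h: float = 1e-6) -> Params:
    """Central-difference gradient of ``loss_fn`` — test oracle for backprop."""
    grads: Params = {}
    for name, value in params.items():
        g = np.zeros_like(value)
        flat = value.ravel()
        gflat = g.ravel()
        for j in range(flat.size):
            orig = flat[j]
            flat[j] = orig + h
            lp = loss_fn(params)
            flat[j] = orig - h
            lm = loss_fn(params)
            flat[j] = orig
            gflat[j] = (lp - lm) / (2.0 * h)
        grads[name] = g
    return grads
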