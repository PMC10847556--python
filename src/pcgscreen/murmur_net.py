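"""Recurrent murmur-grade regressor.

A two-layer LSTM (50 units each) reads the 200 timesteps of 13-dim MFCC
vectors; the final hidden state feeds a 30-unit fully connected layer with
a rectifier and a linear scalar output trained with squared error. The
learning rate starts at 0.002 and is halved every five epochs. Training
pools blocks from all auscultation positions with no position feature, and
the minority class (murmur grade >= 1) is resampled with replacement until
the class ratio is approximately 1:1.

The network, backpropagation through time, and the Adam optimizer are
implemented directly on numpy arrays; inference is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class NetConfig:
    lstm_units: int = 50
    lstm_layers: int = 2
    fc_units: int = 30
    initial_lr: float = 0.002
    lr_halving_period_epochs: int = 5
    epochs: int = 30
    batch_size: int = 128
    seed: int = 0
    balance_target_ratio: float = 1.0
    input_dim: int = 13

    def __post_init__(self):
        if min(self.lstm_units, self.lstm_layers, self.fc_units,
               self.epochs, self.batch_size, self.input_dim) <= 0:
            raise ValueError("all counts must be positive")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")


def learning_rate(epoch: int, config: NetConfig) -> float:
    """lr(epoch) = initial * 0.5 ** floor(epoch / halving period)."""
    return config.initial_lr * 0.5 ** (epoch // config.lr_halving_period_epochs)


@dataclass
class MurmurPrediction:
    recording_id: str
    position: int
    block_grades: list
    recording_grade: float


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _LSTMLayer:
    """Single LSTM layer with fused input/recurrent weight matrix.

    Gate order in the fused matrix is (input, forget, cell, output); the
    forget-gate bias is initialized to one.
    """

    def __init__(self, input_dim, hidden, rng, dtype=np.float32):
        self.d, self.h = input_dim, hidden
        bound = np.sqrt(6.0 / (input_dim + hidden + 4 * hidden))
        self.W = rng.uniform(-bound, bound, (input_dim + hidden, 4 * hidden)).astype(dtype)
        self.b = np.zeros(4 * hidden, dtype=dtype)
        self.b[hidden:2 * hidden] = 1.0
        self.dtype = dtype

    def forward(self, x, cache=False):
        """x: (B, T, d) -> h sequence (B, T, h)."""
        b_n, t_n, _ = x.shape
        h = np.zeros((b_n, self.h), dtype=self.dtype)
        c = np.zeros((b_n, self.h), dtype=self.dtype)
        hs = np.empty((t_n, b_n, self.h), dtype=self.dtype)
        if cache:
            self._cache = {k: np.empty((t_n, b_n, self.h), dtype=self.dtype)
                           for k in ("i", "f", "g", "o", "tc", "cprev", "hprev")}
            self._x = x
        hh = self.h
        for t in range(t_n):
            z = np.concatenate([x[:, t, :], h], axis=1) @ self.W + self.b
            i = _sigmoid(z[:, :hh])
            f = _sigmoid(z[:, hh:2 * hh])
            g = np.tanh(z[:, 2 * hh:3 * hh])
            o = _sigmoid(z[:, 3 * hh:])
            if cache:
                self._cache["cprev"][t] = c
                self._cache["hprev"][t] = h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[t] = h
            if cache:
                for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("tc", tc)):
                    self._cache[k][t] = v
        return np.transpose(hs, (1, 0, 2))

    def backward(self, dh_seq):
        """dh_seq: (B, T, h) gradients on the output sequence.

        Returns dx (B, T, d); accumulates self.dW, self.db.
        """
        cch, x = self._cache, self._x
        b_n, t_n, _ = x.shape
        hh = self.h
        dW = np.zeros_like(self.W)
        db = np.zeros_like(self.b)
        dh_next = np.zeros((b_n, hh), dtype=self.dtype)
        dc_next = np.zeros((b_n, hh), dtype=self.dtype)
        dx = np.empty_like(x)
        for t in range(t_n - 1, -1, -1):
            i, f, g, o, tc = (cch[k][t] for k in ("i", "f", "g", "o", "tc"))
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * cch["cprev"][t]
            dg = dc * i
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            inp = np.concatenate([x[:, t, :], cch["hprev"][t]], axis=1)
            dW += inp.T @ dz
            db += dz.sum(axis=0)
            dinp = dz @ self.W.T
            dx[:, t, :] = dinp[:, :self.d]
            dh_next = dinp[:, self.d:]
            dc_next = dc * f
        self.dW, self.db = dW, db
        return dx


class MurmurNet:
    """LSTM(50) x2 -> FC(30) + ReLU -> linear scalar grade."""

    def __init__(self, config: NetConfig, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(config.seed)
        dims = [config.input_dim] + [config.lstm_units] * config.lstm_layers
        self.lstm = [_LSTMLayer(dims[k], dims[k + 1], rng, dtype)
                     for k in range(config.lstm_layers)]
        h = config.lstm_units
        self.W1 = rng.uniform(-np.sqrt(6.0 / (h + config.fc_units)),
                              np.sqrt(6.0 / (h + config.fc_units)),
                              (h, config.fc_units)).astype(dtype)
        self.b1 = np.zeros(config.fc_units, dtype=dtype)
        self.W2 = rng.uniform(-np.sqrt(6.0 / (config.fc_units + 1)),
                              np.sqrt(6.0 / (config.fc_units + 1)),
                              (config.fc_units, 1)).astype(dtype)
        self.b2 = np.zeros(1, dtype=dtype)

    # -- forward / backward -------------------------------------------------
    def forward(self, x, cache=False):
        """x: (B, T, input_dim) -> predicted grades (B,)."""
        x = np.ascontiguousarray(x, dtype=self.dtype)
        seq = x
        for layer in self.lstm:
            seq = layer.forward(seq, cache=cache)
        h_last = seq[:, -1, :]
        a1 = h_last @ self.W1 + self.b1
        r1 = np.maximum(a1, 0.0)
        out = (r1 @ self.W2 + self.b2)[:, 0]
        if cache:
            self._fc_cache = (h_last, a1, r1, seq.shape[1])
        return out

    def backward(self, dout):
        """dout: (B,) gradient on the scalar output."""
        h_last, a1, r1, t_n = self._fc_cache
        d = dout[:, None].astype(self.dtype)
        self.dW2 = r1.T @ d
        self.db2 = d.sum(axis=0)
        dr1 = d @ self.W2.T
        da1 = dr1 * (a1 > 0)
        self.dW1 = h_last.T @ da1
        self.db1 = da1.sum(axis=0)
        dh_last = da1 @ self.W1.T
        dh_seq = np.zeros((h_last.shape[0], t_n, self.config.lstm_units), dtype=self.dtype)
        dh_seq[:, -1, :] = dh_last
        for layer in reversed(self.lstm):
            dh_seq = layer.backward(dh_seq)
        return dh_seq

    def parameters(self):
        params = []
        for k, layer in enumerate(self.lstm):
            params += [(f"lstm{k}.W", layer, "W"), (f"lstm{k}.b", layer, "b")]
        params += [("W1", self, "W1"), ("b1", self, "b1"),
                   ("W2", self, "W2"), ("b2", self, "b2")]
        return params

    def gradients(self):
        grads = {}
        for k, layer in enumerate(self.lstm):
            grads[f"lstm{k}.W"] = layer.dW
            grads[f"lstm{k}.b"] = layer.db
        grads.update(W1=self.dW1, b1=self.db1, W2=self.dW2, b2=self.db2)
        return grads

    # -- persistence --------------------------------------------------------
    def save(self, path):
        path = Path(path)
        arrays = {name: getattr(obj, attr) for name, obj, attr in self.parameters()}
        np.savez(path.with_suffix(".npz"), **arrays)
        sidecar = {"config": self.config.__dict__,
                   "loss_history": getattr(self, "loss_history", [])}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path):
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        net = cls(NetConfig(**sidecar["config"]))
        data = np.load(path.with_suffix(".npz"))
        for name, obj, attr in net.parameters():
            setattr(obj, attr, data[name].astype(net.dtype))
        net.loss_history = sidecar.get("loss_history", [])
        return net


class _Adam:
    def __init__(self, names, shapes, dtype):
        self.m = {n: np.zeros(s, dtype=dtype) for n, s in zip(names, shapes)}
        self.v = {n: np.zeros(s, dtype=dtype) for n, s in zip(names, shapes)}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params, grads, lr):
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for name, obj, attr in params:
            g = grads[name]
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            update = lr * (self.m[name] / b1c) / (np.sqrt(self.v[name] / b2c) + self.eps)
            setattr(obj, attr, getattr(obj, attr) - update.astype(g.dtype))


def balance_training_set(blocks, labels, seed, target_ratio: float = 1.0):
    """Resample murmur blocks (grade >= 1) with replacement until the ratio
    of grade >= 1 to grade < 1 is approximately ``target_ratio``.

    All original samples are retained; returns (blocks, labels) as lists.
    """
    labels = np.asarray(labels, dtype=float)
    pos_idx = np.flatnonzero(labels >= 1.0)
    neg_idx = np.flatnonzero(labels < 1.0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both murmur classes must be non-empty for balancing")
    rng = np.random.default_rng(seed)
    n_target = int(round(target_ratio * len(neg_idx)))
    n_extra = max(0, n_target - len(pos_idx))
    extra = rng.choice(pos_idx, size=n_extra, replace=True) if n_extra else np.array([], dtype=int)
    order = np.concatenate([np.arange(len(labels)), extra])
    return [blocks[i] for i in order], labels[order].tolist()


def train(blocks, labels, config: NetConfig, verbose: bool = False):
    """Train the regressor on standardized 13 x 200 feature matrices.

    ``blocks`` is a sequence of (13, 200) arrays (time is the sequence
    axis); labels are murmur grades in [0, 6]. Returns the trained
    MurmurNet with a per-epoch loss history attached.
    """
    x = np.stack([np.asarray(b, dtype=np.float32).T for b in blocks])  # (N, T, 13)
    y = np.asarray(labels, dtype=np.float32)
    if x.shape[0] != y.shape[0] or x.shape[0] == 0:
        raise ValueError("blocks and labels must align and be non-empty")
    net = MurmurNet(config)
    opt = _Adam([p[0] for p in net.parameters()],
                [getattr(o, a).shape for _, o, a in net.parameters()], net.dtype)
    rng = np.random.default_rng(config.seed + 1)
    history = []
    n = x.shape[0]
    for epoch in range(config.epochs):
        lr = learning_rate(epoch, config)
        order = rng.permutation(n)
        total, count = 0.0, 0
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            xb, yb = x[idx], y[idx]
            pred = net.forward(xb, cache=True)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; last lr {lr}")
            net.backward(2.0 * err / len(idx))
            opt.step(net.parameters(), net.gradients(), lr)
            total += loss * len(idx)
            count += len(idx)
        history.append(total / count)
        if verbose:
            print(f"epoch {epoch:3d}  lr {lr:.5f}  mse {history[-1]:.4f}")
    net.loss_history = history
    return net


def predict_blocks(net: MurmurNet, blocks, batch_size: int = 256):
    """Forward passes only; deterministic."""
    if len(blocks) == 0:
        return np.zeros(0)
    x = np.stack([np.asarray(b, dtype=np.float32).T for b in blocks])
    out = []
    for s in range(0, x.shape[0], batch_size):
        out.append(net.forward(x[s:s + batch_size]))
    return np.concatenate(out).astype(float)


def predict_recording(net: MurmurNet, feature_blocks, recording_id: str = "",
                      position: int = 0) -> MurmurPrediction:
    """Median block grade as the recording-level prediction."""
    if len(feature_blocks) == 0:
        raise ValueError(f"recording {recording_id}: no feature blocks (unusable)")
    grades = predict_blocks(net, [fb.matrix for fb in feature_blocks])
    return MurmurPrediction(recording_id, position, grades.tolist(),
                            float(np.median(grades)))


def aggregate_participant(grades, noise_flags, mode: str = "max"):
    """Participant-level predictors from four positional grades.

    Noisy positions contribute grade 0. mode="max" returns the maximum;
    mode="per-position" returns (4-vector with noisy entries zeroed, noise
    indicator bits) for the multiposition gradient model.
    """
    grades = np.asarray(grades, dtype=float)
    noise = np.asarray(noise_flags, dtype=bool)
    if noise.all():
        raise ValueError("all four recordings noisy; participant excluded")
    masked = np.where(noise, 0.0, grades)
    if mode == "max":
        return float(masked.max())
    if mode == "per-position":
        return masked, noise.astype(int)
    raise ValueError(f"unknown mode {mode!r}")
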