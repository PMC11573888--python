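"""Two-class tile classifier: a convolutional network with inception-style
parallel-branch blocks, trained with Adam (lr 0.001, batch 8) and softmax
cross-entropy. At the end of each epoch validation log-loss and accuracy
are recorded, and the final model is the checkpoint with the lowest
validation cross-entropy (first epoch on ties).

Implemented directly on numpy (NHWC layout, explicit backward passes), so
training is CPU-only and fully seeded. The ``small`` architecture scale is
the default test surface: it downsamples the 512x512x3 input early and has
well under 1M parameters, so it trains end-to-end in minutes on one core.
The ``full`` scale stacks more inception blocks at higher resolution and
mirrors the deep-inception topology only schematically; the published
training scale (hundreds of thousands of iterations) is not a desk-size
computation.

Outputs are p(RAS) with p(BRAF) = 1 - p(RAS) under the two-way softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

INPUT_SIZE = 512


@dataclass(frozen=True)
class ModelConfig:
    architecture_scale: str = "small"
    n_classes: int = 2
    learning_rate: float = 0.001
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0
    input_size: int = INPUT_SIZE

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.architecture_scale not in ("small", "full"):
            raise ValueError(f"unknown architecture scale: {self.architecture_scale}")


@dataclass
class EpochStats:
    epoch: int  # 1-based
    train_loss: float
    val_loss: float
    val_accuracy: float


@dataclass
class TrainingLog:
    epochs: list[EpochStats] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """1-based argmin of validation log-loss, first on ties."""
        losses = [e.val_loss for e in self.epochs]
        return int(np.argmin(losses)) + 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "best_epoch": self.best_epoch,
                "epochs": [vars(e) for e in self.epochs],
            }
        )


@dataclass(frozen=True)
class TilePrediction:
    slide_id: str
    key: str
    p_ras: float

    @property
    def p_braf(self) -> float:
        return 1.0 - self.p_ras


# ---------------------------------------------------------------------------
# layers (NHWC)


class _Layer:
    training = False

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def buffers(self) -> list[np.ndarray]:
        return []

    def set_training(self, flag: bool) -> None:
        self.training = flag


class _BatchNorm(_Layer):
    """Per-channel batch normalization with running inference statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        axes = tuple(range(x.ndim - 1))
        if self.training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean[...] = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var[...] = (1 - self.momentum) * self.run_var + self.momentum * var
            if self._collect is not None:
                n = int(np.prod([x.shape[a] for a in axes]))
                self._collect[0] += x.sum(axis=axes)
                self._collect[1] += (x.astype(np.float64) ** 2).sum(axis=axes)
                self._collect[2] += n
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mu) / self._std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * self._xhat + self.beta

    _collect: list | None = None

    def start_collect(self) -> None:
        c = self.gamma.shape[0]
        self._collect = [np.zeros(c), np.zeros(c), 0]

    def finish_collect(self) -> None:
        s, s2, n = self._collect
        if n > 0:
            mean = s / n
            self.run_mean[...] = mean
            self.run_var[...] = np.maximum(s2 / n - mean**2, 0.0)
        self._collect = None

    def backward(self, g):
        axes = tuple(range(g.ndim - 1))
        self.dgamma[...] = (g * self._xhat).sum(axis=axes)
        self.dbeta[...] = g.sum(axis=axes)
        dxhat = g * self.gamma
        m = self._m
        return (
            dxhat - dxhat.mean(axis=axes) - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def buffers(self):
        return [self.run_mean, self.run_var]


class _AvgPoolDown(_Layer):
    """Non-overlapping f x f mean pooling (early spatial reduction)."""

    def __init__(self, factor: int):
        self.f = factor

    def forward(self, x):
        n, h, w, c = x.shape
        f = self.f
        self._shape = x.shape
        r = x.reshape(n, h // f, f, w // f, f, c)
        return r.mean(axis=(2, 4))

    def backward(self, g):
        n, h, w, c = self._shape
        f = self.f
        g = g / (f * f)
        return np.repeat(np.repeat(g, f, axis=1), f, axis=2)


class _Conv(_Layer):
    """Same-padded stride-1 convolution; k*k shifted matmuls, no im2col."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * k * cin))
        self.W = (rng.standard_normal((k, k, cin, cout)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k = k
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        self._xp = xp
        n, h, w, _ = x.shape
        out = np.zeros((n, h, w, self.W.shape[3]), dtype=np.float32)
        for a in range(k):
            for b in range(k):
                out += self._xp[:, a : a + h, b : b + w, :] @ self.W[a, b]
        return out + self.b

    def backward(self, g):
        k = self.k
        p = k // 2
        n, h, w, _ = g.shape
        xp = self._xp
        dxp = np.zeros_like(xp)
        for a in range(k):
            for b in range(k):
                patch = xp[:, a : a + h, b : b + w, :]
                self.dW[a, b] = np.tensordot(patch, g, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, a : a + h, b : b + w, :] += g @ self.W[a, b].T
        self.db[:] = g.sum(axis=(0, 1, 2))
        return dxp[:, p : p + h, p : p + w, :] if p else dxp

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class _ReLU(_Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _MaxPool2(_Layer):
    def forward(self, x):
        n, h, w, c = x.shape
        r = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = r.max(axis=(2, 4))
        m = r == out[:, :, None, :, None, :]
        self._mask = m / np.maximum(m.sum(axis=(2, 4), keepdims=True), 1)
        self._shape = x.shape
        return out

    def backward(self, g):
        n, h, w, c = self._shape
        spread = self._mask * g[:, :, None, :, None, :]
        return spread.reshape(n, h, w, c)


class _AvgPool3Same(_Layer):
    """3x3 stride-1 mean pooling, zero-padded (pooling branch of a block)."""

    def forward(self, x):
        self._shape = x.shape
        return self._smooth(x)

    @staticmethod
    def _smooth(x):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = np.zeros_like(x)
        for a in range(3):
            for b in range(3):
                out += xp[:, a : a + h, b : b + w, :]
        return out / 9.0

    def backward(self, g):
        return self._smooth(g)  # the operator is symmetric


class _GlobalAvgPool(_Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        n, h, w, c = self._shape
        return np.broadcast_to(g[:, None, None, :], (n, h, w, c)) / (h * w)


class _Dense(_Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = (rng.standard_normal((cin, cout)) * np.sqrt(2.0 / cin)).astype(
            np.float32
        )
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[:] = self._x.T @ g
        self.db[:] = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]


class _Sequential(_Layer):
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def buffers(self):
        return [b for layer in self.layers for b in layer.buffers()]

    def set_training(self, flag):
        for layer in self.layers:
            layer.set_training(flag)


class _Inception(_Layer):
    """Parallel branches (1x1 / 3x3 / 5x5 / pooled 1x1) concatenated."""

    def __init__(self, cin, c1, c2r, c2, c3r, c3, cp, rng):
        def unit(ci, co, k):
            return [_Conv(ci, co, k, rng), _BatchNorm(co), _ReLU()]

        self.branches = [
            _Sequential(unit(cin, c1, 1)),
            _Sequential(unit(cin, c2r, 1) + unit(c2r, c2, 3)),
            _Sequential(unit(cin, c3r, 1) + unit(c3r, c3, 5)),
            _Sequential([_AvgPool3Same()] + unit(cin, cp, 1)),
        ]
        self.out_channels = c1 + c2 + c3 + cp

    def forward(self, x):
        outs = [b.forward(x) for b in self.branches]
        self._splits = np.cumsum([o.shape[3] for o in outs])[:-1]
        return np.concatenate(outs, axis=3)

    def backward(self, g):
        pieces = np.split(g, self._splits, axis=3)
        dx = None
        for br, piece in zip(self.branches, pieces):
            d = br.backward(piece)
            dx = d if dx is None else dx + d
        return dx

    def params(self):
        return [p for b in self.branches for p in b.params()]

    def grads(self):
        return [g for b in self.branches for g in b.grads()]

    def buffers(self):
        return [b for br in self.branches for b in br.buffers()]

    def set_training(self, flag):
        for b in self.branches:
            b.set_training(flag)


class Model:
    """A sequential network emitting two-class softmax probabilities."""

    def __init__(self, cfg: ModelConfig, net: _Sequential):
        self.cfg = cfg
        self.net = net

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def predict_proba(self, tiles: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Probabilities (n, 2) ordered (p_braf, p_ras); deterministic."""
        self.net.set_training(False)
        out = []
        for i in range(0, len(tiles), batch_size):
            x = preprocess_tiles(tiles[i : i + batch_size])
            out.append(_softmax(self.logits(x)))
        return np.concatenate(out, axis=0)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.net.params()))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.net.params() + self.net.buffers()]

    def set_state(self, state: list[np.ndarray]) -> None:
        slots = self.net.params() + self.net.buffers()
        for p, s in zip(slots, state):
            p[...] = s


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def preprocess_tiles(tiles: np.ndarray) -> np.ndarray:
    """uint8 RGB -> float32 scaled to [-1, 1]."""
    return (np.asarray(tiles, dtype=np.float32) / 127.5) - 1.0


def build_model(cfg: ModelConfig) -> Model:
    """Seeded construction; identical config gives identical weights."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.architecture_scale == "small":
        layers = [
            _AvgPoolDown(8),  # 512 -> 64
            _Conv(3, 16, 3, rng),
            _BatchNorm(16),
            _ReLU(),
            _MaxPool2(),  # -> 32
            _Inception(16, 8, 8, 12, 4, 6, 6, rng),  # -> 32 channels
            _MaxPool2(),  # -> 16
            _Conv(32, 32, 3, rng),
            _BatchNorm(32),
            _ReLU(),
            _GlobalAvgPool(),
            _Dense(32, cfg.n_classes, rng),
        ]
    else:  # full
        layers = [
            _AvgPoolDown(2),  # 512 -> 256
            _Conv(3, 32, 3, rng),
            _BatchNorm(32),
            _ReLU(),
            _MaxPool2(),  # 128
            _Conv(32, 64, 3, rng),
            _BatchNorm(64),
            _ReLU(),
            _MaxPool2(),  # 64
            _Inception(64, 32, 24, 48, 8, 16, 16, rng),  # 112
            _MaxPool2(),  # 32
            _Inception(112, 48, 32, 64, 12, 24, 24, rng),  # 160
            _MaxPool2(),  # 16
            _Inception(160, 64, 48, 96, 16, 32, 32, rng),  # 224
            _GlobalAvgPool(),
            _Dense(224, cfg.n_classes, rng),
        ]
    return Model(cfg, _Sequential(layers))


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _iter_bns(layer):
    if isinstance(layer, _BatchNorm):
        yield layer
    elif isinstance(layer, _Sequential):
        for sub in layer.layers:
            yield from _iter_bns(sub)
    elif isinstance(layer, _Inception):
        for br in layer.branches:
            yield from _iter_bns(br)


def _recompute_bn_stats(model: "Model", x: np.ndarray, batch_size: int) -> None:
    """Precise-BN pass: replace running statistics with exact activation
    moments over the training set (small-batch running averages lag the
    rapidly-moving weights early in training)."""
    bns = list(_iter_bns(model.net))
    if not bns:
        return
    for bn in bns:
        bn.start_collect()
    model.net.set_training(True)
    for i in range(0, len(x), batch_size):
        model.net.forward(preprocess_tiles(x[i : i + batch_size]))
    for bn in bns:
        bn.finish_collect()


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0))))


def evaluate_loss(model: Model, tiles: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = model.predict_proba(tiles)
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return _cross_entropy(probs, y), acc


def train(
    model: Model,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: ModelConfig | None = None,
) -> tuple[Model, TrainingLog]:
    """Train with Adam and keep the lowest-validation-loss checkpoint.

    ``train_data`` / ``val_data`` are (tiles uint8 (n,512,512,3), labels
    (n,) with 0 = BRAF, 1 = RAS). Raises before the first epoch if the
    training labels contain a single class.
    """
    cfg = cfg or model.cfg
    x_train, y_train = train_data
    x_val, y_val = val_data
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.net.params(), cfg.learning_rate)
    log = TrainingLog()
    best_loss = np.inf
    best_state = model.get_state()

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(y_train))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            x = preprocess_tiles(x_train[idx])
            y = y_train[idx]
            model.net.set_training(True)
            probs = _softmax(model.net.forward(x))
            losses.append(_cross_entropy(probs, y))
            g = probs.copy()
            g[np.arange(len(y)), y] -= 1.0
            model.net.backward((g / len(y)).astype(np.float32))
            opt.step(model.net.grads())
        _recompute_bn_stats(model, x_train, cfg.batch_size * 2)
        val_loss, val_acc = evaluate_loss(model, x_val, y_val)
        log.epochs.append(
            EpochStats(epoch, float(np.mean(losses)), val_loss, val_acc)
        )
        if val_loss < best_loss:  # strict: first epoch wins ties
            best_loss = val_loss
            best_state = model.get_state()

    best = build_model(cfg)
    best.set_state(best_state)
    return best, log


def predict_tiles(
    model: Model,
    tiles: np.ndarray,
    slide_ids: list[str],
    keys: list[str] | None = None,
) -> list[TilePrediction]:
    """Per-tile p(RAS); inference is deterministic."""
    tiles = np.asarray(tiles)
    size = model.cfg.input_size
    for i, t in enumerate(tiles):
        if t.shape != (size, size, 3):
            key = keys[i] if keys else str(i)
            raise ValueError(f"tile {key}: expected ({size}, {size}, 3), got {t.shape}")
    probs = model.predict_proba(tiles)
    keys = keys or [str(i) for i in range(len(tiles))]
    return [
        TilePrediction(slide_id=s, key=k, p_ras=float(p[1]))
        for s, k, p in zip(slide_ids, keys, probs)
    ]


def activation_map(
    model: Model,
    tile: np.ndarray,
    occluder_size: int = 64,
    stride: int = 64,
) -> np.ndarray:
    """Occlusion saliency for the predicted class.

    A gray square slides over the tile; the heat value is the drop in the
    predicted-class probability when that location is hidden. The map is
    min-max normalized to [0, 1] unless it is essentially flat, in which
    case normalization is skipped (only the minimum is subtracted) to avoid
    amplifying noise.
    """
    size = model.cfg.input_size
    if occluder_size > size:
        raise ValueError("occluder larger than tile")
    base = model.predict_proba(tile[None])[0]
    cls = int(base.argmax())
    positions = list(range(0, size - occluder_size + 1, stride))
    if positions[-1] != size - occluder_size:
        positions.append(size - occluder_size)
    occluded = []
    for y0 in positions:
        for x0 in positions:
            t = tile.copy()
            t[y0 : y0 + occluder_size, x0 : x0 + occluder_size] = 128
            occluded.append(t)
    probs = model.predict_proba(np.asarray(occluded))[:, cls]
    heat = np.maximum(base[cls] - probs, 0.0).reshape(len(positions), len(positions))
    span = heat.max() - heat.min()
    if span >= 0.05:
        return (heat - heat.min()) / span
    return heat - heat.min()


def save_model(model: Model, log: TrainingLog | None, path: str | Path) -> None:
    """Weights as npz plus a framework-neutral JSON metadata sidecar."""
    path = Path(path)
    state = model.net.params() + model.net.buffers()
    np.savez(path, **{f"p{i:04d}": a for i, a in enumerate(state)})
    meta = {
        "config": vars(model.cfg),
        "n_parameters": model.n_parameters(),
        "best_epoch": log.best_epoch if log and log.epochs else None,
        "log": json.loads(log.to_json()) if log and log.epochs else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> Model:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = ModelConfig(**{k: v for k, v in meta["config"].items()})
    model = build_model(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        state = [data[k] for k in sorted(data.files)]
    model.set_state(state)
    return model
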