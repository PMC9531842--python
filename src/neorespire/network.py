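"""The baseline 1-D convolutional classifier, trained with backpropagation.

The canonical architecture takes the 2 per-window features as a length-2,
single-channel sequence:

    conv1d(64 filters, kernel 1, ReLU) -> maxpool1d(pool 1, stride 1)
    -> flatten -> dropout(0.01) -> dense(200, ReLU) -> dense(100, ReLU)
    -> dense(1, sigmoid)

for 46,129 trainable parameters (128 + 25,800 + 20,100 + 101). The single
sigmoid output unit with a 0.5 decision threshold is what that parameter
count implies; a two-unit softmax head would carry 46,230 parameters and is
inconsistent with the model-size accounting, so the sigmoid head is canonical.

Everything here is plain NumPy: forward/backward passes per layer, Adam,
binary cross-entropy, inverted dropout, and early stopping on validation loss
with a patience counter. All randomness (init, shuffling, dropout masks,
fold assignment) flows from explicit integer seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold

from neorespire.errors import ValidationError


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

def _activate(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if name in (None, "none", "linear"):
        return z
    raise ValidationError(f"unknown activation {name!r}")


def _activation_grad(z: np.ndarray, a: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "sigmoid":
        return a * (1.0 - a)
    if name in (None, "none", "linear"):
        return np.ones_like(z)
    raise ValidationError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Layer:
    """Base layer: forward caches what backward needs; params are dicts."""

    kind = "base"
    activation: str | None = None

    def build(self, input_shape, rng):  # -> output_shape
        raise NotImplementedError

    def forward(self, x, training=False, rng=None):
        raise NotImplementedError

    def backward(self, grad_out, preact=False):
        """Gradient wrt input, accumulating parameter grads.

        ``preact=True`` means grad_out is already wrt the pre-activation
        (used for the fused sigmoid + cross-entropy output gradient).
        """
        raise NotImplementedError

    def params(self) -> dict:
        return {}

    def grads(self) -> dict:
        return {}

    def spec(self) -> dict:
        raise NotImplementedError


class Conv1D(Layer):
    kind = "conv1d"

    def __init__(self, filters: int, kernel: int = 1, activation: str = "relu"):
        if filters < 1 or kernel < 1:
            raise ValidationError("filters and kernel must be positive")
        self.filters, self.kernel, self.activation = filters, kernel, activation
        self.W = self.b = None

    def build(self, input_shape, rng):
        length, in_ch = input_shape
        if length < self.kernel:
            raise ValidationError("input shorter than kernel")
        fan_in = self.kernel * in_ch
        limit = math.sqrt(6.0 / (fan_in + self.filters))
        self.W = rng.uniform(-limit, limit, size=(self.kernel, in_ch, self.filters))
        self.b = np.zeros(self.filters)
        return (length - self.kernel + 1, self.filters)

    def forward(self, x, training=False, rng=None):
        B, L, C = x.shape
        Lout = L - self.kernel + 1
        z = np.broadcast_to(self.b, (B, Lout, self.filters)).copy()
        for j in range(self.kernel):
            z += x[:, j:j + Lout, :] @ self.W[j]
        self._x, self._z = x, z
        self._a = _activate(z, self.activation)
        return self._a

    def backward(self, grad_out, preact=False):
        dz = grad_out if preact else grad_out * _activation_grad(self._z, self._a, self.activation)
        Lout = dz.shape[1]
        self._dW = np.zeros_like(self.W)
        for j in range(self.kernel):
            self._dW[j] = np.einsum("blc,blf->cf", self._x[:, j:j + Lout, :], dz)
        self._db = dz.sum(axis=(0, 1))
        dx = np.zeros_like(self._x)
        for j in range(self.kernel):
            dx[:, j:j + Lout, :] += dz @ self.W[j].T
        return dx

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self._dW, "b": self._db}

    def spec(self):
        return {"kind": self.kind, "filters": self.filters, "kernel": self.kernel,
                "activation": self.activation}


class MaxPool1D(Layer):
    kind = "maxpool1d"

    def __init__(self, pool: int = 1, stride: int = 1):
        if pool < 1 or stride < 1:
            raise ValidationError("pool and stride must be positive")
        self.pool, self.stride = pool, stride

    def build(self, input_shape, rng):
        length, ch = input_shape
        if length < self.pool:
            raise ValidationError("input shorter than pool window")
        self._lout = (length - self.pool) // self.stride + 1
        return (self._lout, ch)

    def forward(self, x, training=False, rng=None):
        if self.pool == 1 and self.stride == 1:
            self._identity = True
            return x
        self._identity = False
        B, L, C = x.shape
        starts = np.arange(self._lout) * self.stride
        windows = np.stack([x[:, s:s + self.pool, :] for s in starts], axis=1)  # (B, Lout, pool, C)
        self._argmax = windows.argmax(axis=2)
        self._in_shape = x.shape
        return windows.max(axis=2)

    def backward(self, grad_out, preact=False):
        if self._identity:
            return grad_out
        B, Lout, C = grad_out.shape
        dx = np.zeros(self._in_shape)
        b_idx, c_idx = np.meshgrid(np.arange(B), np.arange(C), indexing="ij")
        for w in range(Lout):
            pos = w * self.stride + self._argmax[:, w, :]
            np.add.at(dx, (b_idx, pos, c_idx), grad_out[:, w, :])
        return dx

    def spec(self):
        return {"kind": self.kind, "pool": self.pool, "stride": self.stride}


class Flatten(Layer):
    kind = "flatten"

    def build(self, input_shape, rng):
        length, ch = input_shape
        self._in_shape = (length, ch)
        return (length * ch,)

    def forward(self, x, training=False, rng=None):
        self._batch = x.shape[0]
        return x.reshape(self._batch, -1)

    def backward(self, grad_out, preact=False):
        return grad_out.reshape(self._batch, *self._in_shape)

    def spec(self):
        return {"kind": self.kind}


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, rate: float = 0.01):
        if not (0 <= rate < 1):
            raise ValidationError("dropout rate must be in [0, 1)")
        self.rate = rate

    def build(self, input_shape, rng):
        return input_shape

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValidationError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad_out, preact=False):
        return grad_out if self._mask is None else grad_out * self._mask

    def spec(self):
        return {"kind": self.kind, "rate": self.rate}


class Dense(Layer):
    kind = "dense"

    def __init__(self, units: int, activation: str = "relu"):
        if units < 1:
            raise ValidationError("units must be positive")
        self.units, self.activation = units, activation
        self.W = self.b = None

    def build(self, input_shape, rng):
        (fan_in,) = input_shape
        limit = math.sqrt(6.0 / (fan_in + self.units))
        self.W = rng.uniform(-limit, limit, size=(fan_in, self.units))
        self.b = np.zeros(self.units)
        return (self.units,)

    def forward(self, x, training=False, rng=None):
        self._x = x
        self._z = x @ self.W + self.b
        self._a = _activate(self._z, self.activation)
        return self._a

    def backward(self, grad_out, preact=False):
        dz = grad_out if preact else grad_out * _activation_grad(self._z, self._a, self.activation)
        self._dW = self._x.T @ dz
        self._db = dz.sum(axis=0)
        return dz @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self._dW, "b": self._db}

    def spec(self):
        return {"kind": self.kind, "units": self.units, "activation": self.activation}


_LAYER_KINDS = {"conv1d": Conv1D, "maxpool1d": MaxPool1D, "flatten": Flatten,
                "dropout": Dropout, "dense": Dense}


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class NetworkModel:
    """An ordered layer stack with (length, channels) sequence input."""

    def __init__(self, layers: Sequence[Layer], input_shape: tuple[int, int], seed: int = 0):
        self.layers = list(layers)
        self.input_shape = tuple(input_shape)
        self.seed = seed
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in self.layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape

    # -- inference ----------------------------------------------------------

    def _coerce_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.ndim == 2:
            length, ch = self.input_shape
            if X.shape[1] != length * ch:
                raise ValidationError(
                    f"input has {X.shape[1]} values per sample, expected {length * ch}")
            X = X.reshape(X.shape[0], length, ch)
        return X

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Full forward pass; dropout is inactive unless ``training``."""
        out = self._coerce_input(X)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X).reshape(len(np.atleast_2d(X)), -1)[:, 0]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def hidden_activations(self, X: np.ndarray) -> list[np.ndarray]:
        """Post-activation outputs of every layer (dropout inactive)."""
        out = self._coerce_input(X)
        acts = []
        for layer in self.layers:
            out = layer.forward(out, training=False)
            acts.append(out)
        return acts

    # -- bookkeeping --------------------------------------------------------

    @property
    def parameter_count(self) -> int:
        return int(sum(p.size for layer in self.layers for p in layer.params().values()))

    def get_weights(self) -> list[dict]:
        return [{k: v.copy() for k, v in layer.params().items()} for layer in self.layers]

    def set_weights(self, weights: list[dict]) -> None:
        for layer, w in zip(self.layers, weights):
            for k, v in w.items():
                getattr(layer, k)[...] = v

    def manifest(self) -> dict:
        return {"input_shape": list(self.input_shape), "seed": self.seed,
                "layers": [layer.spec() for layer in self.layers]}

    def save(self, path_prefix: str) -> None:
        """Write ``<prefix>.json`` (architecture) + ``<prefix>.npz`` (weights)."""
        with open(f"{path_prefix}.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=1)
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params().items():
                arrays[f"layer{i}_{k}"] = v
        np.savez(f"{path_prefix}.npz", **arrays)

    @classmethod
    def load(cls, path_prefix: str) -> "NetworkModel":
        with open(f"{path_prefix}.json") as fh:
            man = json.load(fh)
        layers = []
        for spec in man["layers"]:
            spec = dict(spec)
            kind = spec.pop("kind")
            layers.append(_LAYER_KINDS[kind](**spec))
        model = cls(layers, tuple(man["input_shape"]), seed=man.get("seed", 0))
        with np.load(f"{path_prefix}.npz") as data:
            for i, layer in enumerate(model.layers):
                for k in layer.params():
                    getattr(layer, k)[...] = data[f"layer{i}_{k}"]
        return model


def build_1dcnn(input_length: int = 2, seed: int = 0) -> NetworkModel:
    """The canonical 46,129-parameter classifier (see module docstring)."""
    return NetworkModel(
        [
            Conv1D(filters=64, kernel=1, activation="relu"),
            MaxPool1D(pool=1, stride=1),
            Flatten(),
            Dropout(0.01),
            Dense(200, activation="relu"),
            Dense(100, activation="relu"),
            Dense(1, activation="sigmoid"),
        ],
        input_shape=(input_length, 1),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 5
    optimizer: str = "adam"
    shuffle: bool = True
    max_epochs: int = 100
    early_stop_patience: int | None = 5
    restore_best: bool = False
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.early_stop_patience is not None and self.early_stop_patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValidationError("only the adam optimizer is supported")


class _Adam:
    def __init__(self, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, model: NetworkModel):
        self.t += 1
        for i, layer in enumerate(model.layers):
            grads = layer.grads()
            for k, g in grads.items():
                key = (i, k)
                p = layer.params()[k]
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m += (1 - self.b1) * (g - m)
                v += (1 - self.b2) * (g * g - v)
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def stopping_epoch(val_losses: Sequence[float], patience: int | None) -> int | None:
    """Epoch (1-based) after which the patience rule halts training.

    Returns None when the loss sequence never exhausts the patience budget.
    The training loop realizes exactly this rule: a strictly lower validation
    loss resets the counter; ``patience`` consecutive non-improving epochs
    stop the run.
    """
    if patience is None:
        return None
    best = math.inf
    since = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best = loss
            since = 0
        else:
            since += 1
            if since >= patience:
                return epoch
    return None


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _as_xy(data) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(data, "X") and hasattr(data, "y"):
        return np.asarray(data.X, dtype=float), np.asarray(data.y)
    X, y = data
    return np.asarray(X, dtype=float), np.asarray(y)


def train(model: NetworkModel, train_set, val_set=None, cfg: TrainConfig = TrainConfig()):
    """Minibatch Adam on binary cross-entropy with early stopping.

    Monitors validation loss each epoch; training stops after
    ``early_stop_patience`` consecutive epochs without improvement, or at
    ``max_epochs``. When no validation set is supplied, ``val_fraction`` of
    the training data is held out (seeded). Returns ``(model, history)`` with
    per-epoch train/validation losses.
    """
    X, y = _as_xy(train_set)
    if len(X) == 0:
        raise ValidationError("empty training set")
    if not np.isin(np.unique(y), [0, 1]).all():
        raise ValidationError("labels must be binary")
    rng = np.random.default_rng(cfg.seed)
    if val_set is None:
        n_val = max(1, int(round(cfg.val_fraction * len(X))))
        perm = rng.permutation(len(X))
        Xv, yv = X[perm[:n_val]], y[perm[:n_val]]
        X, y = X[perm[n_val:]], y[perm[n_val:]]
        if len(X) == 0:
            raise ValidationError("validation holdout left no training data")
    else:
        Xv, yv = _as_xy(val_set)

    opt = _Adam(cfg.learning_rate)
    history = {"train_loss": [], "val_loss": [], "stopped_epoch": None}
    best_val = math.inf
    best_weights = None
    since_improve = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(X)) if cfg.shuffle else np.arange(len(X))
        epoch_loss = 0.0
        for start in range(0, len(X), cfg.batch_size):
            rows = order[start:start + cfg.batch_size]
            xb, yb = X[rows], y[rows]
            p = model.forward(xb, training=True, rng=rng).reshape(-1)
            loss = bce_loss(p, yb)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch + 1} "
                    f"(lr={cfg.learning_rate}, batch={cfg.batch_size})")
            epoch_loss += loss * len(rows)
            # fused sigmoid + BCE gradient wrt the output pre-activation
            delta = ((p - yb) / len(rows)).reshape(-1, 1)
            grad = model.layers[-1].backward(delta, preact=True)
            for layer in reversed(model.layers[:-1]):
                grad = layer.backward(grad)
            opt.step(model)
        history["train_loss"].append(epoch_loss / len(X))
        val_loss = bce_loss(model.predict_proba(Xv), yv)
        history["val_loss"].append(val_loss)

        if val_loss < best_val:
            best_val = val_loss
            since_improve = 0
            if cfg.restore_best:
                best_weights = model.get_weights()
        else:
            since_improve += 1
            if cfg.early_stop_patience is not None and since_improve >= cfg.early_stop_patience:
                history["stopped_epoch"] = epoch + 1
                break

    if cfg.restore_best and best_weights is not None:
        model.set_weights(best_weights)
    return model, history


# ---------------------------------------------------------------------------
# Hyperparameter grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSearchSpace:
    """Exhaustive (epochs, learning-rate) grid; the study grid is epochs
    10..100 step 10 crossed with nine Adam learning rates."""

    epochs_grid: Sequence[int] = tuple(range(10, 101, 10))
    lr_grid: Sequence[float] = (0.001, 0.01, 0.1, 0.002, 0.02, 0.2, 0.003, 0.03, 0.3)

    def __post_init__(self):
        if not self.epochs_grid or not self.lr_grid:
            raise ValidationError("grids must be non-empty")


@dataclass
class GridSearchResult:
    best_epochs: int
    best_lr: float
    best_error: float
    table: list[dict] = field(default_factory=list)


def grid_search(
    space: GridSearchSpace,
    train_set,
    val_set,
    model_builder: Callable[[int], NetworkModel] | None = None,
    base_cfg: TrainConfig = TrainConfig(),
) -> GridSearchResult:
    """Evaluate every (epochs, lr) pair; return the argmin of the validation
    misclassification rate f_D with the full score table.

    Early stopping is disabled inside the search: the epoch budget is itself
    the hyperparameter under study. Ties break on (f_D, epochs, lr) so the
    result is invariant to grid ordering.
    """
    builder = model_builder or (lambda seed: build_1dcnn(seed=seed))
    Xv, yv = _as_xy(val_set)
    rows = []
    for epochs in space.epochs_grid:
        for lr in space.lr_grid:
            cfg = replace(base_cfg, learning_rate=lr, max_epochs=epochs,
                          early_stop_patience=None)
            model = builder(base_cfg.seed)
            try:
                model, _ = train(model, train_set, val_set, cfg)
                err = float(np.mean(model.predict(Xv) != yv))
            except RuntimeError:  # divergence at large lr counts as total loss
                err = 1.0
            rows.append({"epochs": int(epochs), "lr": float(lr), "f_D": err})
    best = min(rows, key=lambda r: (r["f_D"], r["epochs"], r["lr"]))
    return GridSearchResult(best["epochs"], best["lr"], best["f_D"], rows)


# ---------------------------------------------------------------------------
# Repeated k-fold cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Repeated k-fold summary; sigma is the sample standard deviation of the
    per-repeat mean accuracies and sigma_error = sigma / sqrt(n_repeats)."""

    fold_accuracies: np.ndarray  # (repeats, k)
    mean_accuracy: float
    sigma: float
    n_repeats: int
    sigma_error: float
    degenerate: bool = False


def repeated_kfold(
    model_builder: Callable[[int], NetworkModel],
    dataset,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
    train_cfg: TrainConfig = TrainConfig(),
) -> CVResult:
    """Repeated k-fold CV: each repeat re-partitions the data with a fresh
    seeded shuffle; a fresh model is trained per fold.

    With a single repeat the across-repeat deviation is undefined, so sigma
    falls back to the across-fold deviation and the result is flagged
    ``degenerate`` (sigma_error is then reported as sigma).
    """
    X, y = _as_xy(dataset)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > len(X):
        raise ValidationError(f"k={k} exceeds dataset size {len(X)}")
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    accs = np.zeros((repeats, k))
    for r in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + r)
        for f, (tr, te) in enumerate(kf.split(X)):
            cfg = replace(train_cfg, seed=seed + 1000 * r + f)
            model = model_builder(cfg.seed)
            model, _ = train(model, (X[tr], y[tr]), None, cfg)
            accs[r, f] = float(np.mean(model.predict(X[te]) == y[te]))
    repeat_means = accs.mean(axis=1)
    mean = float(repeat_means.mean())
    if repeats > 1:
        sigma = float(repeat_means.std(ddof=1))
        return CVResult(accs, mean, sigma, repeats, sigma / math.sqrt(repeats))
    sigma = float(accs[0].std(ddof=1))
    return CVResult(accs, mean, sigma, 1, sigma, degenerate=True)
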