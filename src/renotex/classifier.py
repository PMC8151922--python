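"""The 58-10-3 feed-forward classifier with early-stopped training.

The network takes the 58-dimensional fused feature vector (57 texture
descriptors + kidney size), passes it through one tanh hidden layer of 10
units, and emits 3-way softmax class probabilities.  Training minimizes
mean cross-entropy with full-batch Adam; a held-out validation partition
drives early stopping (training halts once the validation loss has not
improved for ``patience`` consecutive epochs, and the weights from the best
validation epoch are restored).  Inputs are scaled per-feature to [-1, 1]
using minima/maxima fitted on the training partition only.

The hidden stage is a single layer of 10 units; a literally stacked variant
(several 10-unit layers) is available through ``NetworkConfig.hidden_layers``
for comparison, since descriptions of this architecture are sometimes read
either way.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset_fusion import FeatureTable
from .types import CLASS_ORDER, ClassLabel


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture, split and optimization settings."""

    input_dim: int = 58
    hidden_units: int = 10
    output_dim: int = 3
    hidden_layers: int = 1
    max_epochs: int = 1000
    patience: int = 6
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    learning_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.input_dim, self.hidden_units, self.output_dim, self.hidden_layers) < 1:
            raise ValueError("all network dimensions must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split_fractions}")
        if self.patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be positive")

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "hidden_units": self.hidden_units,
            "output_dim": self.output_dim,
            "hidden_layers": self.hidden_layers,
            "max_epochs": self.max_epochs,
            "patience": self.patience,
            "split_fractions": list(self.split_fractions),
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/validation/test index sets covering all records."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def partition_of(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for name in ("train", "val", "test"):
            for idx in getattr(self, name):
                out[int(idx)] = name
        return out


def split_data(
    table: FeatureTable, cfg: NetworkConfig, stratified: bool = False
) -> SplitAssignment:
    """Seeded random train/val/test assignment.

    Sizes follow ``n_train = round(0.70 n)``, ``n_val = round(0.15 n)``,
    ``n_test = n - n_train - n_val``.  In stratified mode the same rule is
    applied within each class, keeping per-partition class proportions within
    one record of the global ones.
    """
    n = len(table)
    if n == 0:
        raise ValueError("cannot split an empty feature table")
    rng = np.random.default_rng(cfg.seed)
    f_train, f_val, _ = cfg.split_fractions

    def _assign(indices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        perm = rng.permutation(indices)
        m = len(perm)
        n_train = round(f_train * m)
        n_val = round(f_val * m)
        return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]

    if stratified:
        labels = table.labels
        parts = [[], [], []]
        for cls in CLASS_ORDER:
            cls_idx = np.flatnonzero(labels == cls.value)
            for bucket, chunk in zip(parts, _assign(cls_idx)):
                bucket.append(chunk)
        train, val, test = (np.sort(np.concatenate(b)) for b in parts)
    else:
        train, val, test = _assign(np.arange(n))
    return SplitAssignment(train=np.asarray(train), val=np.asarray(val), test=np.asarray(test))


class MinMaxScaler:
    """Per-feature linear map of the training range onto [-1, 1].

    Inputs outside the fitted range are clipped before scaling, so the
    network always sees bounded, finite values.  Constant features map to 0.
    """

    def __init__(self, lo: np.ndarray | None = None, hi: np.ndarray | None = None):
        self.lo = lo
        self.hi = hi

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.lo is None:
            raise RuntimeError("scaler is not fitted")
        span = self.hi - self.lo
        constant = span == 0
        span = np.where(constant, 1.0, span)
        X = np.clip(X, self.lo, self.hi)
        out = 2.0 * (X - self.lo) / span - 1.0
        return np.where(constant, 0.0, out)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward(weights, biases, X):
    """Returns (activations per layer, output probabilities)."""
    acts = [X]
    h = X
    for W, b in zip(weights[:-1], biases[:-1]):
        h = np.tanh(h @ W + b)
        acts.append(h)
    probs = _softmax(h @ weights[-1] + biases[-1])
    return acts, probs


def _cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum() / len(probs))


@dataclass
class TrainedNetwork:
    """Fitted weights, the training-split scaler, and the training history."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler: MinMaxScaler
    config: NetworkConfig
    history: dict = field(default_factory=dict)
    best_epoch: int = 0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, one row per sample (rows sum to 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected {self.config.input_dim}-dimensional inputs, got {X.shape[1]}"
            )
        _, probs = _forward(self.weights, self.biases, self.scaler.transform(X))
        return probs

    def predict_labels(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.array([CLASS_ORDER[k].value for k in probs.argmax(axis=1)])

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config.to_dict(),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaler": {"lo": self.scaler.lo.tolist(), "hi": self.scaler.hi.tolist()},
            "history": self.history,
            "best_epoch": self.best_epoch,
            "class_order": [c.value for c in CLASS_ORDER],
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedNetwork":
        payload = json.loads(Path(path).read_text())
        cfg_dict = payload["config"]
        cfg_dict["split_fractions"] = tuple(cfg_dict["split_fractions"])
        return cls(
            weights=[np.array(w) for w in payload["weights"]],
            biases=[np.array(b) for b in payload["biases"]],
            scaler=MinMaxScaler(
                lo=np.array(payload["scaler"]["lo"]), hi=np.array(payload["scaler"]["hi"])
            ),
            config=NetworkConfig(**cfg_dict),
            history=payload["history"],
            best_epoch=payload["best_epoch"],
        )


def _encode_labels(labels: np.ndarray, k: int) -> np.ndarray:
    index = {c.value: i for i, c in enumerate(CLASS_ORDER)}
    try:
        ids = np.array([index[ClassLabel(l).value] for l in labels])
    except (ValueError, KeyError) as exc:
        raise ValueError(f"inadmissible class label: {exc}") from exc
    onehot = np.zeros((len(ids), k))
    onehot[np.arange(len(ids)), ids] = 1.0
    return onehot


def train_network(
    table: FeatureTable, split: SplitAssignment, cfg: NetworkConfig | None = None
) -> TrainedNetwork:
    """Fit the network on the training partition with validation-driven stopping.

    Fully deterministic for a fixed (table, split, config).  When the
    validation partition is empty, training runs to ``max_epochs`` and the
    best epoch is the one with the lowest training loss.
    """
    cfg = cfg or NetworkConfig()
    X = table.feature_matrix
    y = _encode_labels(table.labels, cfg.output_dim)
    if X.shape[1] != cfg.input_dim:
        raise ValueError(f"table has {X.shape[1]} features; config expects {cfg.input_dim}")
    X_tr, y_tr = X[split.train], y[split.train]
    if len(X_tr) == 0:
        raise ValueError("training partition is empty")
    if y_tr.sum(axis=0).max() == y_tr.sum():
        raise ValueError("training partition contains a single class; cannot fit")

    scaler = MinMaxScaler().fit(X_tr)
    Xs_tr = scaler.transform(X_tr)
    has_val = len(split.val) > 0
    if has_val:
        Xs_val = scaler.transform(X[split.val])
        y_val = y[split.val]

    rng = np.random.default_rng(cfg.seed)
    sizes = [cfg.input_dim] + [cfg.hidden_units] * cfg.hidden_layers + [cfg.output_dim]
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot-uniform
        weights.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
        biases.append(np.zeros(n_out))

    # Adam state
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    params = weights + biases
    m_state = [np.zeros_like(p) for p in params]
    v_state = [np.zeros_like(p) for p in params]

    train_losses: list[float] = []
    val_losses: list[float] = []
    best_loss = np.inf
    best_epoch = 0
    best_params = [p.copy() for p in params]
    since_best = 0

    for epoch in range(1, cfg.max_epochs + 1):
        acts, probs = _forward(weights, biases, Xs_tr)
        train_loss = _cross_entropy(probs, y_tr)
        # backprop (mean cross-entropy over softmax)
        delta = (probs - y_tr) / len(Xs_tr)
        grads_w = [np.empty(0)] * len(weights)
        grads_b = [np.empty(0)] * len(biases)
        for layer in range(len(weights) - 1, -1, -1):
            grads_w[layer] = acts[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ weights[layer].T) * (1.0 - acts[layer] ** 2)
        grads = grads_w + grads_b
        for i, (p, g) in enumerate(zip(params, grads)):
            m_state[i] = beta1 * m_state[i] + (1 - beta1) * g
            v_state[i] = beta2 * v_state[i] + (1 - beta2) * g**2
            m_hat = m_state[i] / (1 - beta1**epoch)
            v_hat = v_state[i] / (1 - beta2**epoch)
            p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

        train_losses.append(train_loss)
        if has_val:
            _, val_probs = _forward(weights, biases, Xs_val)
            monitor = _cross_entropy(val_probs, y_val)
            val_losses.append(monitor)
        else:
            monitor = train_loss
        if monitor < best_loss:
            best_loss = monitor
            best_epoch = epoch
            best_params = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    k = len(weights)
    return TrainedNetwork(
        weights=[p for p in best_params[:k]],
        biases=[p for p in best_params[k:]],
        scaler=scaler,
        config=cfg,
        history={"train_loss": train_losses, "val_loss": val_losses},
        best_epoch=best_epoch,
    )
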