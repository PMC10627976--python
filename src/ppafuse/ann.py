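"""Two-layer feedforward network with validation-based early stopping.

The model class is deliberately small and fixed: one hidden layer of
``hidden_units`` tanh units and a two-unit softmax output read as posterior
class probabilities (TD = 0, ASD = 1).  Training is full-batch gradient
descent (Adam steps) on the mean squared error between the softmax outputs
and one-hot targets, monitored on an explicit validation set: training
stops at ``max_epochs``, when the training MSE reaches ``goal_mse``, or
after ``patience`` consecutive epochs of increasing validation error —
and the weights returned are always those with minimal validation error
seen during training.

Everything is seeded: identical seed, data and config give bit-identical
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnnConfig",
    "TrainedModel",
    "encode_labels",
    "train_ann",
    "predict_scores",
    "predict_labels",
]

CLASS_ORDER = ("TD", "ASD")  # column order of score tables: P(TD), P(ASD)


@dataclass(frozen=True)
class AnnConfig:
    """Hyperparameters of the two-layer network.

    Defaults: 10 hidden tanh units, two softmax outputs, at most 10 000
    full-batch epochs, a training-MSE goal of 1e-5 and early stopping after
    6 consecutive validation-error increases.
    """

    hidden_units: int = 10
    max_epochs: int = 10_000
    goal_mse: float = 1e-5
    patience: int = 6
    learning_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainedModel:
    """Weights at the minimal-validation-error epoch, plus a training trace."""

    weights: dict[str, np.ndarray]
    config: AnnConfig
    epochs_run: int = 0
    best_epoch: int = 0
    train_mse: float = np.nan
    val_mse: float = np.nan
    val_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_features(self) -> int:
        return self.weights["W1"].shape[0]


def encode_labels(labels) -> np.ndarray:
    """Map TD/ASD string labels to 0/1 integers."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub":
        return labels.astype(int)
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in CLASS_ORDER:
            raise ValueError(f"unknown label {lab!r}")
        out[i] = CLASS_ORDER.index(lab)
    return out


def _forward(weights: dict[str, np.ndarray], X: np.ndarray):
    H = np.tanh(X @ weights["W1"] + weights["b1"])
    Z = H @ weights["W2"] + weights["b2"]
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    P = E / E.sum(axis=1, keepdims=True)
    return H, P


def _mse(P: np.ndarray, Y: np.ndarray) -> float:
    return float(np.mean((P - Y) ** 2))


def train_ann(X_train, y_train, X_val, y_val, cfg: AnnConfig = AnnConfig()) -> TrainedModel:
    """Train the network with early stopping on an explicit validation set.

    Parameters
    ----------
    X_train, X_val : ndarray, (n, d)
        Feature rows (already normalised); column counts must agree.
    y_train, y_val
        Labels as TD/ASD strings or 0/1 integers; both classes must occur
        in ``y_train``.
    cfg : AnnConfig
        Architecture and stopping rules.

    Returns
    -------
    TrainedModel
        Weights of the epoch with minimal validation MSE, the epoch counts
        and the per-epoch validation-error trace.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_val = np.asarray(X_val, dtype=np.float64)
    if X_train.ndim != 2 or X_val.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if X_train.shape[1] != X_val.shape[1]:
        raise ValueError("train/validation feature counts differ")
    if X_train.shape[1] == 0:
        raise ValueError(
            "no features: the upstream selection is empty; relax the p-value "
            "threshold or skip this configuration"
        )
    if not (np.isfinite(X_train).all() and np.isfinite(X_val).all()):
        raise ValueError("non-finite values in input features")
    y_tr = encode_labels(y_train)
    y_va = encode_labels(y_val)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("both classes must be present in the training set")

    n, d = X_train.shape
    h = cfg.hidden_units
    Y_tr = np.eye(2)[y_tr]
    Y_va = np.eye(2)[y_va]

    rng = np.random.default_rng(cfg.seed)
    weights = {
        "W1": rng.standard_normal((d, h)) / np.sqrt(d),
        "b1": np.zeros(h),
        "W2": rng.standard_normal((h, 2)) / np.sqrt(h),
        "b2": np.zeros(2),
    }
    m = {k: np.zeros_like(v) for k, v in weights.items()}
    v = {k: np.zeros_like(v_) for k, v_ in weights.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8

    best = {k: w.copy() for k, w in weights.items()}
    best_val = np.inf
    best_epoch = 0
    prev_val = np.inf
    increases = 0
    val_trace = []
    train_mse = np.inf
    epoch = 0

    for epoch in range(1, cfg.max_epochs + 1):
        H, P = _forward(weights, X_train)
        train_mse = _mse(P, Y_tr)

        # gradient of mean((P - Y)^2) through the softmax
        G = (2.0 / (n * 2)) * (P - Y_tr)
        dZ = P * (G - (G * P).sum(axis=1, keepdims=True))
        grads = {
            "W2": H.T @ dZ,
            "b2": dZ.sum(axis=0),
        }
        dH = (dZ @ weights["W2"].T) * (1 - H**2)
        grads["W1"] = X_train.T @ dH
        grads["b1"] = dH.sum(axis=0)

        for k in weights:
            m[k] = b1 * m[k] + (1 - b1) * grads[k]
            v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
            mhat = m[k] / (1 - b1**epoch)
            vhat = v[k] / (1 - b2**epoch)
            weights[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)

        _, P_va = _forward(weights, X_val)
        val_mse = _mse(P_va, Y_va)
        val_trace.append(val_mse)

        if val_mse < best_val:
            best_val = val_mse
            best_epoch = epoch
            for k in weights:
                best[k] = weights[k].copy()
        increases = increases + 1 if val_mse > prev_val else 0
        prev_val = val_mse
        if increases >= cfg.patience or train_mse <= cfg.goal_mse:
            break

    H_tr, P_tr = _forward(best, X_train)
    return TrainedModel(
        weights=best,
        config=cfg,
        epochs_run=epoch,
        best_epoch=best_epoch,
        train_mse=_mse(P_tr, Y_tr),
        val_mse=best_val,
        val_trace=np.asarray(val_trace),
    )


def predict_scores(model: TrainedModel, X) -> np.ndarray:
    """Posterior-like class scores, shape (n, 2): columns P(TD), P(ASD).

    Rows sum to 1 by construction of the softmax output layer.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected (n, {model.n_features}) features, got {X.shape}"
        )
    _, P = _forward(model.weights, X)
    return P


def predict_labels(scores: np.ndarray) -> np.ndarray:
    """Hard labels from scores: ASD iff P(ASD) >= 0.5 (ties go to ASD)."""
    scores = np.asarray(scores)
    return np.where(scores[:, 1] >= 0.5, "ASD", "TD")
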