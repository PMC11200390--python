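"""Class-weighted feed-forward classifier over principal-component scores.

Architecture: sequential blocks of dense -> batch normalization -> ReLU ->
dropout (default widths 512/256/128/64, dropout 0.45), then a dense softmax
head with 4 units.  Training uses Adam (lr 1e-4), minibatches of 50, a
fixed number of epochs (150), Glorot-uniform weight init with zero biases,
and a per-sample class weight ``n_total / (4 * n_c)`` multiplying the
cross-entropy term to compensate for class imbalance.  After every epoch
the validation loss is evaluated in inference mode (moving batch-norm
statistics, dropout off) and the parameters achieving the lowest validation
loss are the ones returned.

The network is implemented directly on NumPy: with four inputs and these
widths it trains in seconds on a single CPU and keeps the package free of a
deep-learning framework dependency.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .pca import PCScores

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99
_ADAM_BETA1, _ADAM_BETA2, _ADAM_EPS = 0.9, 0.999, 1e-7

N_CLASSES = 4


def compute_class_weights(labels: np.ndarray) -> np.ndarray:
    """Balanced inverse-frequency weights w_c = n_total / (4 * n_c).

    Reduces to all-ones for balanced labels and satisfies
    sum_c w_c * n_c = n_total.
    """
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=N_CLASSES + 1)[1 : N_CLASSES + 1]
    if (counts == 0).any():
        missing = [c + 1 for c in range(N_CLASSES) if counts[c] == 0]
        raise ValueError(f"classes absent from labels: {missing}")
    return len(labels) / (N_CLASSES * counts.astype(float))


def weighted_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, class_weights: np.ndarray
) -> float:
    """Mean over samples of w_y * (-log p[y])."""
    labels = np.asarray(labels, dtype=int)
    p = np.clip(probs[np.arange(len(labels)), labels - 1], 1e-12, None)
    return float(np.mean(class_weights[labels - 1] * -np.log(p)))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _init_params(
    rng: np.random.Generator, n_inputs: int, architecture: tuple[int, ...]
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    fan_in = n_inputs
    for i, width in enumerate(architecture):
        params[f"W{i}"] = _glorot_uniform(rng, fan_in, width)
        params[f"b{i}"] = np.zeros(width)
        params[f"gamma{i}"] = np.ones(width)
        params[f"beta{i}"] = np.zeros(width)
        params[f"rmean{i}"] = np.zeros(width)
        params[f"rvar{i}"] = np.ones(width)
        fan_in = width
    params["Wout"] = _glorot_uniform(rng, fan_in, N_CLASSES)
    params["bout"] = np.zeros(N_CLASSES)
    return params


@dataclasses.dataclass
class ClassifierModel:
    """Trained network parameters plus training history.

    ``params`` holds dense weights/biases, batch-norm scale/shift and the
    moving statistics used at inference time; ``history`` records per-epoch
    train/val loss and accuracy; ``best_epoch`` is the (0-based) epoch whose
    validation loss was lowest — the returned parameters are its checkpoint.
    """

    architecture: tuple[int, ...]
    dropout_rate: float
    n_inputs: int
    n_classes: int
    params: dict[str, np.ndarray]
    history: dict[str, list[float]]
    best_epoch: int
    class_weights: np.ndarray

    def save(self, path: str | Path) -> None:
        meta = json.dumps(
            {
                "architecture": list(self.architecture),
                "dropout_rate": self.dropout_rate,
                "n_inputs": self.n_inputs,
                "n_classes": self.n_classes,
                "history": self.history,
                "best_epoch": self.best_epoch,
            }
        )
        np.savez(
            path,
            meta=np.array(meta),
            class_weights=self.class_weights,
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            params = {
                k: z[k] for k in z.files if k not in {"meta", "class_weights"}
            }
            return cls(
                tuple(meta["architecture"]),
                meta["dropout_rate"],
                meta["n_inputs"],
                meta["n_classes"],
                params,
                meta["history"],
                meta["best_epoch"],
                z["class_weights"],
            )


@dataclasses.dataclass
class PredictionSet:
    """Per-slice class probabilities and the argmax prediction."""

    slice_id: np.ndarray
    label: np.ndarray
    prob_matrix: np.ndarray  # (n_slices, 4)
    predicted: np.ndarray  # (n_slices,) int 1..4


def _forward_inference(
    params: dict[str, np.ndarray], architecture: tuple[int, ...], X: np.ndarray
) -> np.ndarray:
    """Probabilities in inference mode (moving statistics, no dropout)."""
    h = X
    for i in range(len(architecture)):
        a = h @ params[f"W{i}"] + params[f"b{i}"]
        ahat = (a - params[f"rmean{i}"]) / np.sqrt(params[f"rvar{i}"] + _BN_EPS)
        h = np.maximum(params[f"gamma{i}"] * ahat + params[f"beta{i}"], 0.0)
    return _softmax(h @ params["Wout"] + params["bout"])


def _train_step(
    params: dict[str, np.ndarray],
    architecture: tuple[int, ...],
    dropout_rate: float,
    X: np.ndarray,
    labels: np.ndarray,
    class_weights: np.ndarray,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], float]:
    """One forward/backward pass; returns gradients and the batch loss."""
    B = X.shape[0]
    n_blocks = len(architecture)
    cache = []
    h = X
    for i in range(n_blocks):
        W, b = params[f"W{i}"], params[f"b{i}"]
        gamma, beta = params[f"gamma{i}"], params[f"beta{i}"]
        a = h @ W + b
        mu = a.mean(axis=0)
        var = a.var(axis=0)
        inv_sd = 1.0 / np.sqrt(var + _BN_EPS)
        ahat = (a - mu) * inv_sd
        o = gamma * ahat + beta
        r = np.maximum(o, 0.0)
        if dropout_rate > 0:
            mask = (rng.random(r.shape) >= dropout_rate) / (1.0 - dropout_rate)
        else:
            mask = np.ones_like(r)
        cache.append((h, a, mu, inv_sd, ahat, o, r, mask))
        h = r * mask
        # update moving statistics (biased batch variance, Keras-style momentum)
        params[f"rmean{i}"] = _BN_MOMENTUM * params[f"rmean{i}"] + (1 - _BN_MOMENTUM) * mu
        params[f"rvar{i}"] = _BN_MOMENTUM * params[f"rvar{i}"] + (1 - _BN_MOMENTUM) * var

    logits = h @ params["Wout"] + params["bout"]
    probs = _softmax(logits)
    w = class_weights[labels - 1]
    loss = weighted_cross_entropy(probs, labels, class_weights)

    grads: dict[str, np.ndarray] = {}
    Y = np.zeros_like(probs)
    Y[np.arange(B), labels - 1] = 1.0
    dlogits = (probs - Y) * w[:, None] / B
    grads["Wout"] = h.T @ dlogits
    grads["bout"] = dlogits.sum(axis=0)
    dh = dlogits @ params["Wout"].T

    for i in reversed(range(n_blocks)):
        h_in, a, mu, inv_sd, ahat, o, r, mask = cache[i]
        gamma = params[f"gamma{i}"]
        dr = dh * mask
        do = dr * (o > 0)
        grads[f"gamma{i}"] = (do * ahat).sum(axis=0)
        grads[f"beta{i}"] = do.sum(axis=0)
        dahat = do * gamma
        # batch-norm backward (biased variance)
        da = (
            dahat
            - dahat.mean(axis=0)
            - ahat * (dahat * ahat).mean(axis=0)
        ) * inv_sd
        grads[f"W{i}"] = h_in.T @ da
        grads[f"b{i}"] = da.sum(axis=0)
        if i > 0:
            dh = da @ params[f"W{i}"].T
    return grads, loss


def train(
    config: PipelineConfig,
    train_scores: PCScores,
    val_scores: PCScores,
    seed: int | None = None,
) -> ClassifierModel:
    """Train for exactly ``config.epochs`` epochs; return the best checkpoint.

    A single seed controls initialization, batch shuffling and dropout; the
    unseeded mode serves repeatability experiments across random inits.
    """
    X, y = train_scores.scores, np.asarray(train_scores.label, dtype=int)
    Xv, yv = val_scores.scores, np.asarray(val_scores.label, dtype=int)
    if X.shape[1] != config.n_components or Xv.shape[1] != X.shape[1]:
        raise ValueError("score matrices do not match config.n_components")
    class_weights = compute_class_weights(y)

    rng = np.random.default_rng(seed)
    arch = tuple(config.architecture)
    params = _init_params(rng, config.n_components, arch)
    m = {k: np.zeros_like(v) for k, v in params.items() if not k.startswith("r")}
    v2 = {k: np.zeros_like(v) for k, v in m.items()}

    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    best_loss = np.inf
    best_epoch = -1
    best_params: dict[str, np.ndarray] = {}
    step = 0
    n = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            grads, loss = _train_step(
                params, arch, config.dropout_rate, X[idx], y[idx], class_weights, rng
            )
            epoch_loss += loss * len(idx)
            step += 1
            lr_t = (
                config.learning_rate
                * np.sqrt(1 - _ADAM_BETA2**step)
                / (1 - _ADAM_BETA1**step)
            )
            for k in grads:
                m[k] = _ADAM_BETA1 * m[k] + (1 - _ADAM_BETA1) * grads[k]
                v2[k] = _ADAM_BETA2 * v2[k] + (1 - _ADAM_BETA2) * grads[k] ** 2
                params[k] -= lr_t * m[k] / (np.sqrt(v2[k]) + _ADAM_EPS)

        train_probs = _forward_inference(params, arch, X)
        val_probs = _forward_inference(params, arch, Xv)
        val_loss = weighted_cross_entropy(val_probs, yv, class_weights)
        history["train_loss"].append(epoch_loss / n)
        history["train_acc"].append(
            float(np.mean(train_probs.argmax(axis=1) + 1 == y))
        )
        history["val_loss"].append(val_loss)
        history["val_acc"].append(float(np.mean(val_probs.argmax(axis=1) + 1 == yv)))
        if val_loss < best_loss:
            best_loss = val_loss
            best_epoch = epoch
            best_params = copy.deepcopy(params)

    return ClassifierModel(
        arch,
        config.dropout_rate,
        config.n_components,
        N_CLASSES,
        best_params,
        history,
        best_epoch,
        class_weights,
    )


def predict(model: ClassifierModel, scores: PCScores) -> PredictionSet:
    """Inference-mode class probabilities; predicted class = argmax
    (ties resolved toward the lower class index)."""
    if scores.scores.shape[1] != model.n_inputs:
        raise ValueError(
            f"scores have {scores.scores.shape[1]} components, model expects "
            f"{model.n_inputs}"
        )
    probs = predict_proba(model, scores.scores)
    return PredictionSet(
        scores.slice_id.copy(),
        scores.label.copy(),
        probs,
        probs.argmax(axis=1) + 1,
    )


def predict_proba(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Raw probability matrix for an (n, n_inputs) score matrix."""
    return _forward_inference(model.params, model.architecture, np.asarray(X, dtype=float))
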