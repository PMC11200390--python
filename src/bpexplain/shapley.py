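"""Shapley attribution of classifier probabilities to the PC inputs.

The value function of a coalition S is the background expectation of the
model probability with the components in S fixed to the explained slice and
the rest taken from a background row (by default the full training-set PC
scores, as used to initialize the explainer).  Base values are the average
model output per class over the background.

Two routes are provided:

* :func:`kernel_shap` — the Kernel-SHAP estimator: a weighted least-squares
  fit over coalitions with the Shapley kernel weights.  With at most 15
  inputs all 2^n - 2 non-trivial coalitions are enumerated and the estimate
  is exact; for more inputs, coalitions are subsampled (seeded).
* :func:`exact_shapley` — the classic weighted sum over subsets,
  sum_S |S|!(n-|S|-1)!/n! * [v(S u {j}) - v(S)], kept as an independent
  oracle for the kernel route.

Both explain softmax probabilities, not logits: base values are "the
average model output over the training dataset" and force-plot style
interpretations live in probability space.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Callable

import numpy as np
import pandas as pd

from .network import ClassifierModel, predict_proba
from .pca import PCScores

PredictFn = Callable[[np.ndarray], np.ndarray]  # (n, d) -> (n, n_classes)

_CHUNK_ROWS = 200_000  # cap on synthetic rows per model call (memory bound)


@dataclasses.dataclass
class ShapExplanation:
    """Per-slice, per-class Shapley arrays over principal components.

    ``shap_values[s, k, j]`` is the attribution of component j to the class
    k probability for slice s; additivity holds per slice and class:
    ``base_values[k] + sum_j shap_values[s, k, j] == p_k(slice s)``.
    """

    slice_id: np.ndarray  # (n_slices,)
    base_values: np.ndarray  # (n_classes,)
    shap_values: np.ndarray  # (n_slices, n_classes, n_components)
    background_ref: str = "train"

    @property
    def n_components(self) -> int:
        return self.shap_values.shape[2]

    def for_slice(self, slice_id: str) -> np.ndarray:
        idx = np.nonzero(self.slice_id == slice_id)[0]
        if len(idx) == 0:
            raise KeyError(f"slice {slice_id!r} not in explanation")
        return self.shap_values[idx[0]]

    def to_frame(self) -> pd.DataFrame:
        n_slices, n_classes, d = self.shap_values.shape
        rows = []
        for s in range(n_slices):
            for k in range(n_classes):
                rows.append(
                    {
                        "slice_id": self.slice_id[s],
                        "class": k + 1,
                        "base_value": self.base_values[k],
                        **{f"alpha_{j + 1}": self.shap_values[s, k, j] for j in range(d)},
                    }
                )
        return pd.DataFrame(rows)


def _coalition_values(
    predict_fn: PredictFn,
    background: np.ndarray,
    x: np.ndarray,
    masks: np.ndarray,
) -> np.ndarray:
    """v(S) for each coalition mask: E_b[ f(x_S, b_{~S}) ], shape (n_masks, K)."""
    B, d = background.shape
    n_masks = masks.shape[0]
    per_mask = max(1, _CHUNK_ROWS // B)
    out = np.empty((n_masks, 0))
    chunks = []
    for start in range(0, n_masks, per_mask):
        mchunk = masks[start : start + per_mask]
        # rows: for each mask, the full background with masked columns replaced
        data = np.broadcast_to(background, (len(mchunk), B, d)).copy()
        data[np.broadcast_to(mchunk[:, None, :], data.shape)] = np.broadcast_to(
            x, data.shape
        )[np.broadcast_to(mchunk[:, None, :], data.shape)]
        probs = predict_fn(data.reshape(-1, d))
        chunks.append(probs.reshape(len(mchunk), B, -1).mean(axis=1))
    out = np.concatenate(chunks, axis=0)
    return out


def exact_shapley(
    predict_fn: PredictFn | ClassifierModel,
    background: np.ndarray | PCScores,
    x: np.ndarray,
) -> np.ndarray:
    """Exact Shapley values by full coalition enumeration (n_components <= 15).

    Returns an (n_classes, n_components) array; row k holds the per-component
    attributions for the class-k probability.
    """
    predict_fn, background = _as_fn_and_array(predict_fn, background)
    x = np.asarray(x, dtype=float)
    d = background.shape[1]
    if d > 15:
        raise ValueError(f"{d} components is too many for full enumeration")

    masks = np.array(
        [[bool(b >> j & 1) for j in range(d)] for b in range(2**d)], dtype=bool
    )
    values = _coalition_values(predict_fn, background, x, masks)  # (2^d, K)
    K = values.shape[1]
    fact = [math.factorial(i) for i in range(d + 1)]
    phi = np.zeros((K, d))
    sizes = masks.sum(axis=1)
    for j in range(d):
        without_j = ~masks[:, j]
        for b in np.nonzero(without_j)[0]:
            s = sizes[b]
            w = fact[s] * fact[d - s - 1] / fact[d]
            phi[:, j] += w * (values[b | (1 << j)] - values[b])
    return phi


def _shapley_kernel_weights(d: int, sizes: np.ndarray) -> np.ndarray:
    return (d - 1) / (
        np.array([math.comb(d, int(s)) for s in sizes]) * sizes * (d - sizes)
    )


def kernel_shap(
    predict_fn: PredictFn | ClassifierModel,
    background: np.ndarray | PCScores,
    x: np.ndarray,
    max_coalitions: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Kernel-SHAP: weighted least squares over coalitions.

    With d <= 15 (or ``max_coalitions`` covering all) every non-trivial
    coalition is enumerated and the solution equals the exact Shapley
    values; otherwise coalitions are sampled without the full/empty sets.
    The efficiency constraint sum_j phi_j = f(x) - E[f] is imposed by
    eliminating the last coefficient, as in the standard estimator.
    """
    predict_fn, background = _as_fn_and_array(predict_fn, background)
    x = np.asarray(x, dtype=float)
    d = background.shape[1]
    if d == 1:
        # single input: the difference from the base value is its attribution
        full = _coalition_values(predict_fn, background, x, np.ones((1, 1), bool))[0]
        empty = _coalition_values(predict_fn, background, x, np.zeros((1, 1), bool))[0]
        return (full - empty)[:, None]

    if d <= 15:
        masks = np.array(
            [
                [bool(b >> j & 1) for j in range(d)]
                for b in range(1, 2**d - 1)
            ],
            dtype=bool,
        )
    else:
        if max_coalitions is None:
            max_coalitions = 2048
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, d, size=max_coalitions)
        masks = np.zeros((max_coalitions, d), dtype=bool)
        for i, s in enumerate(sizes):
            masks[i, rng.choice(d, size=int(s), replace=False)] = True
        masks = np.unique(masks, axis=0)

    trivial = np.array([[False] * d, [True] * d], dtype=bool)
    v_triv = _coalition_values(predict_fn, background, x, trivial)
    v_empty, v_full = v_triv[0], v_triv[1]  # (K,)
    values = _coalition_values(predict_fn, background, x, masks)  # (M, K)

    sizes = masks.sum(axis=1)
    w = _shapley_kernel_weights(d, sizes)
    Z = masks.astype(float)

    # eliminate phi_d via the efficiency constraint
    span = v_full - v_empty  # (K,)
    y_adj = values - v_empty - Z[:, -1:] * span  # (M, K)
    Zr = Z[:, :-1] - Z[:, -1:]
    A = Zr.T * w  # (d-1, M)
    lhs = A @ Zr
    rhs = A @ y_adj
    phi_partial = np.linalg.solve(lhs, rhs)  # (d-1, K)
    phi_last = span - phi_partial.sum(axis=0)
    return np.vstack([phi_partial, phi_last[None, :]]).T  # (K, d)


def linear_model_shapley(
    coefs: np.ndarray, intercepts: np.ndarray, background: np.ndarray, x: np.ndarray
) -> np.ndarray:
    """Closed-form Shapley values for a linear model f_k(x) = c_k + b_k . x
    with an independent background: phi_kj = b_kj * (x_j - mean background_j)."""
    coefs = np.atleast_2d(coefs)
    return coefs * (np.asarray(x) - background.mean(axis=0))[None, :]


def _as_fn_and_array(predict_fn, background):
    if isinstance(predict_fn, ClassifierModel):
        model = predict_fn
        predict_fn = lambda X: predict_proba(model, X)  # noqa: E731
    if isinstance(background, PCScores):
        background = background.scores
    background = np.asarray(background, dtype=float)
    if background.ndim != 2 or background.shape[0] == 0:
        raise ValueError("background must be a non-empty (n, d) array")
    return predict_fn, background


def explain(
    model: ClassifierModel | PredictFn,
    background: PCScores | np.ndarray,
    slices: PCScores | np.ndarray,
    background_size: int | None = None,
    seed: int | None = None,
) -> ShapExplanation:
    """Kernel-SHAP explanation of every slice against a background set.

    ``background`` is normally the training-set PC scores; ``background_size``
    optionally subsamples it (seeded) to bound the cost on large tables.
    Base values are the mean model output over the (possibly subsampled)
    background.
    """
    if isinstance(slices, PCScores):
        slice_ids = slices.slice_id.copy()
        X = slices.scores
    else:
        X = np.asarray(slices, dtype=float)
        slice_ids = np.array([f"row{i}" for i in range(len(X))], dtype=object)
    predict_fn, bg = _as_fn_and_array(model, background)
    if X.ndim != 2 or X.shape[1] != bg.shape[1]:
        raise ValueError("slices and background have mismatched component counts")

    background_ref = "train"
    if background_size is not None and background_size < len(bg):
        idx = np.random.default_rng(seed).choice(
            len(bg), size=background_size, replace=False
        )
        bg = bg[idx]
        background_ref = f"train-subsample-{background_size}"

    base_values = predict_fn(bg).mean(axis=0)
    shap_values = np.stack(
        [kernel_shap(predict_fn, bg, X[s], seed=seed) for s in range(len(X))]
    )
    return ShapExplanation(slice_ids, base_values, shap_values, background_ref)
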