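"""Training-set standardization and PCA with retained loadings.

Each principal component is a plain weighted sum of the standardized
features, ``PC_j = sum_i phi_ij * x_i``, with ``phi`` the unit-norm
principal axes fit on the training split only; validation and test slices
are transformed with the training mean/SD and loadings.  The loading matrix
is what the explainability stage scales by Shapley values, so its scale and
sign must be pinned down: columns are unit eigenvectors, and each column is
flipped so its largest-magnitude coefficient is positive (PCA signs are
otherwise arbitrary and importance orientations would not reproduce across
runs).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from .tables import FeatureTable

logger = logging.getLogger("bpexplain.pca")


@dataclasses.dataclass
class PCAModel:
    """Standardization parameters plus the loading matrix phi.

    ``loadings`` has shape (n_features, n_components); column j holds the
    coefficients phi_ij.  ``feature_names`` are the retained features in
    column order; ``dropped_features`` lists zero-variance training columns
    excluded from the fit.
    """

    feature_names: list[str]
    feature_means: np.ndarray  # (n_features,)
    feature_sds: np.ndarray  # (n_features,) population SD, all > 0
    loadings: np.ndarray  # (n_features, n_components)
    explained_variance_ratio: np.ndarray  # (n_components,)
    dropped_features: list[str] = dataclasses.field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def validate(self) -> None:
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loading columns are not orthonormal")
        evr = self.explained_variance_ratio
        if (np.diff(evr) > 1e-12).any() or (evr < -1e-12).any() or evr.sum() > 1 + 1e-9:
            raise ValueError("explained_variance_ratio must be nonincreasing in [0,1]")
        if (self.feature_sds <= 0).any():
            raise ValueError("retained features must have positive SD")

    # -- persistence (single .npz archive: arrays + JSON metadata) ---------
    def save(self, path: str | Path) -> None:
        meta = json.dumps(
            {"feature_names": self.feature_names, "dropped_features": self.dropped_features}
        )
        np.savez(
            path,
            feature_means=self.feature_means,
            feature_sds=self.feature_sds,
            loadings=self.loadings,
            explained_variance_ratio=self.explained_variance_ratio,
            meta=np.array(meta),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            return cls(
                meta["feature_names"],
                z["feature_means"],
                z["feature_sds"],
                z["loadings"],
                z["explained_variance_ratio"],
                meta["dropped_features"],
            )


@dataclasses.dataclass
class PCScores:
    """Slices in principal-component space (the classifier's input)."""

    slice_id: np.ndarray  # (n_slices,)
    label: np.ndarray  # (n_slices,) int 1..4
    scores: np.ndarray  # (n_slices, n_components)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def fit_pca(train: FeatureTable, n_components: int = 4) -> PCAModel:
    """Fit standardization (population SD) + PCA on the training split.

    Zero-variance training features are dropped with a warning and recorded
    in the model so that transform can align columns.
    """
    X = train.values
    if n_components < 1:
        raise ValueError("n_components must be positive")
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population (n) denominator
    keep = sds > 0
    dropped = [n for n, k in zip(train.feature_names, keep) if not k]
    if dropped:
        logger.warning("dropping %d zero-variance features: %s", len(dropped), dropped[:5])
    if not keep.any():
        raise ValueError("all features are constant on the training set")
    names = [n for n, k in zip(train.feature_names, keep) if k]
    limit = min(X.shape[0] - 1, int(keep.sum()))
    if n_components > limit:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_slices-1, n_features)={limit}"
        )
    Z = (X[:, keep] - means[keep]) / sds[keep]

    pca = _SKPCA(n_components=n_components, svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()  # (n_features_kept, n_components)
    # Deterministic sign: largest-magnitude coefficient of each column positive.
    for j in range(n_components):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col

    model = PCAModel(
        names,
        means[keep],
        sds[keep],
        loadings,
        pca.explained_variance_ratio_.copy(),
        dropped,
    )
    model.validate()
    return model


def transform(model: PCAModel, table: FeatureTable) -> PCScores:
    """Project a table onto the model's components: scores = Z @ phi.

    Z standardizes with the *training* mean/SD; columns are aligned by name
    and must cover the model's retained features.
    """
    col_index = {n: i for i, n in enumerate(table.feature_names)}
    missing = [n for n in model.feature_names if n not in col_index]
    if missing:
        raise ValueError(f"table is missing model features, e.g. {missing[:5]}")
    idx = [col_index[n] for n in model.feature_names]
    Z = (table.values[:, idx] - model.feature_means) / model.feature_sds
    return PCScores(table.slice_id.copy(), table.label.copy(), Z @ model.loadings)
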