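"""Shapley-scaled loading vectors: feature-level explainability.

Every radiomic feature i owns a vector in component space whose j-th
element is its loading phi_ij.  Scaling that vector elementwise by the
Shapley values alpha_j of the explained prediction gives the
Shapley-scaled vector (alpha_j * phi_ij); its Euclidean length measures
how much the feature mattered for the prediction and the sum of its
elements gives a signed orientation:

    V(X_i)          = sqrt( sum_j phi_ij^2 )
    V_SHAP(X_i)     = sqrt( sum_j (alpha_j * phi_ij)^2 )
    O(X_i)          = sum_j alpha_j * phi_ij

Reports aggregate features by *feature type* (the terminal name token,
pooled over filters and texture-matrix classes, so the GLRLM/GLDM/GLSZM
GrayLevelNonUniformity variants merge): scaled lengths and orientations are
averaged per type, type lengths are min-max rescaled to [0, 1], and types
below the 75th percentile of length are masked out.  Local reports explain
one slice with the Shapley row of its *predicted* class; global reports
average the scaled coefficients over all test slices predicted as a class
before taking lengths.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .pca import PCAModel
from .shapley import ShapExplanation
from .tables import parse_feature_name


def vector_length(loadings_row: np.ndarray) -> float:
    """Euclidean length of a feature's loading vector."""
    return float(np.linalg.norm(np.asarray(loadings_row, dtype=float)))


def shap_scaled_length(loadings_row: np.ndarray, alpha: np.ndarray) -> float:
    """Euclidean length of the Shapley-scaled vector (alpha_j * phi_ij)."""
    loadings_row = np.asarray(loadings_row, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if loadings_row.shape != alpha.shape:
        raise ValueError("loadings row and alpha must have equal length")
    return float(np.linalg.norm(alpha * loadings_row))


def orientation(loadings_row: np.ndarray, alpha: np.ndarray) -> float:
    """Signed sum of the Shapley-scaled coefficients."""
    loadings_row = np.asarray(loadings_row, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if loadings_row.shape != alpha.shape:
        raise ValueError("loadings row and alpha must have equal length")
    return float(np.sum(alpha * loadings_row))


@dataclasses.dataclass
class FeatureImportance:
    """Per-feature and per-type Shapley-scaled importance report.

    ``per_feature`` columns: feature, feature_type, unscaled_length,
    scaled_length, orientation.  ``per_type`` columns: feature_type,
    mean_scaled_length, rescaled_length (min-max to [0, 1]),
    mean_orientation, above_percentile.  ``context`` identifies the report:
    {'scope': 'local', 'slice_id': ..., 'predicted_class': k} or
    {'scope': 'global', 'predicted_class': k, 'n_slices': m}.
    """

    per_feature: pd.DataFrame
    per_type: pd.DataFrame
    percentile_cut: float
    context: dict

    def top_types(self) -> list[str]:
        mask = self.per_type["above_percentile"]
        return self.per_type.loc[mask, "feature_type"].tolist()


def _report(
    pca: PCAModel,
    scaled_coefs: np.ndarray,
    unscaled_lengths: np.ndarray,
    percentile_cut: float,
    context: dict,
) -> FeatureImportance:
    """Build the per-feature/per-type report from scaled coefficients
    (n_features x n_components)."""
    lengths = np.linalg.norm(scaled_coefs, axis=1)
    orientations = scaled_coefs.sum(axis=1)
    types = [parse_feature_name(n).feature_type for n in pca.feature_names]
    per_feature = pd.DataFrame(
        {
            "feature": pca.feature_names,
            "feature_type": types,
            "unscaled_length": unscaled_lengths,
            "scaled_length": lengths,
            "orientation": orientations,
        }
    )
    per_type = (
        per_feature.groupby("feature_type", sort=True)
        .agg(
            mean_scaled_length=("scaled_length", "mean"),
            mean_orientation=("orientation", "mean"),
        )
        .reset_index()
    )
    vals = per_type["mean_scaled_length"].to_numpy()
    span = vals.max() - vals.min()
    if span > 0:
        per_type["rescaled_length"] = (vals - vals.min()) / span
    else:
        per_type["rescaled_length"] = 0.0
    threshold = np.percentile(vals, percentile_cut)  # linear interpolation
    per_type["above_percentile"] = vals > threshold
    per_type = per_type[
        [
            "feature_type",
            "mean_scaled_length",
            "rescaled_length",
            "mean_orientation",
            "above_percentile",
        ]
    ]
    return FeatureImportance(per_feature, per_type, percentile_cut, context)


def local_importance(
    pca: PCAModel,
    explanation: ShapExplanation,
    slice_id: str,
    prediction: int,
    percentile_cut: float = 75.0,
) -> FeatureImportance:
    """Explain a single slice with the Shapley row of its predicted class.

    The predicted class's alpha array scales the loading matrix; features
    are then aggregated by type, rescaled and percentile-masked.
    """
    if not 1 <= prediction <= 4:
        raise ValueError("prediction must be a class in 1..4")
    alphas = explanation.for_slice(slice_id)  # (n_classes, n_components)
    alpha = alphas[prediction - 1]
    if pca.loadings.shape[1] != len(alpha):
        raise ValueError("PCA components and Shapley arrays disagree in size")
    scaled = pca.loadings * alpha[None, :]
    return _report(
        pca,
        scaled,
        np.linalg.norm(pca.loadings, axis=1),
        percentile_cut,
        {"scope": "local", "slice_id": str(slice_id), "predicted_class": int(prediction)},
    )


def global_importance(
    pca: PCAModel,
    explanation: ShapExplanation,
    predictions: np.ndarray,
    predicted_class: int,
    percentile_cut: float = 75.0,
) -> FeatureImportance:
    """Explain one predicted class over a prediction set.

    The Shapley-scaled coefficients alpha_j * phi_ij are averaged over all
    slices predicted as ``predicted_class`` *before* taking Euclidean
    lengths; aggregation, rescaling and masking then follow the local
    procedure.
    """
    if not 1 <= predicted_class <= 4:
        raise ValueError("predicted_class must be in 1..4")
    predictions = np.asarray(predictions, dtype=int)
    if len(predictions) != len(explanation.slice_id):
        raise ValueError("predictions must align with the explanation's slices")
    mask = predictions == predicted_class
    if not mask.any():
        raise ValueError(
            f"no slices predicted as class {predicted_class}; cannot build a "
            "global report for an empty subset"
        )
    # alpha does not depend on the feature index, so averaging the scaled
    # coefficient matrices equals scaling by the mean alpha
    mean_alpha = explanation.shap_values[mask, predicted_class - 1, :].mean(axis=0)
    scaled = pca.loadings * mean_alpha[None, :]
    return _report(
        pca,
        scaled,
        np.linalg.norm(pca.loadings, axis=1),
        percentile_cut,
        {
            "scope": "global",
            "predicted_class": int(predicted_class),
            "n_slices": int(mask.sum()),
        },
    )
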