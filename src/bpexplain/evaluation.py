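"""Test-set evaluation: confusion matrix, accuracy, adjacency, kappa,
bootstrap confidence intervals and t-tests against chance.

The four BPE classes are ordinal, so beyond accuracy the report quantifies
how many errors were benign (confusions between adjacent classes) and
chance-corrected agreement (unweighted Cohen's kappa).  Uncertainty comes
from resampling the (truth, prediction) pairs with replacement (default
10,000 resamples) with percentile 95% intervals; the p-value for
skill-above-chance is a one-sided one-sample Student's t-test of the
bootstrap accuracies against 0.25.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion

N_CLASSES = 4


def confusion_matrix(truth: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """4x4 counts, rows = true class, cols = predicted, ordered minimal->marked."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    for arr, name in ((truth, "truth"), (predicted, "predicted")):
        if ((arr < 1) | (arr > N_CLASSES)).any():
            raise ValueError(f"{name} labels outside 1..{N_CLASSES}")
    return _sk_confusion(truth, predicted, labels=[1, 2, 3, 4])


def cohens_kappa(confusion: np.ndarray) -> float:
    """Unweighted Cohen's kappa from a square confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the row/column marginals.
    A degenerate table with p_e = 1 is perfect agreement (kappa = 1) if
    p_o = 1 and undefined otherwise.
    """
    c = np.asarray(confusion, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(c) / total
    p_e = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / total**2
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return 1.0
        raise ValueError("chance agreement is 1 but observed agreement is not")
    return float((p_o - p_e) / (1.0 - p_e))


def adjacent_fraction(confusion: np.ndarray) -> float | None:
    """Fraction of misclassifications between adjacent classes.

    Returns None when there are no misclassifications (undefined).
    """
    c = np.asarray(confusion, dtype=float)
    r, col = np.indices(c.shape)
    off = r != col
    denom = c[off].sum()
    if denom == 0:
        return None
    return float(c[off & (np.abs(r - col) == 1)].sum() / denom)


def _bootstrap_arrays(
    truth: np.ndarray, predicted: np.ndarray, n_resamples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized bootstrap: accuracy and kappa per resample."""
    n = len(truth)
    codes = (truth - 1) * N_CLASSES + (predicted - 1)  # 0..15
    idx = rng.integers(0, n, size=(n_resamples, n))
    sampled = codes[idx]
    counts = np.zeros((n_resamples, N_CLASSES * N_CLASSES))
    np.add.at(
        counts,
        (np.repeat(np.arange(n_resamples), n), sampled.ravel()),
        1.0,
    )
    counts = counts.reshape(n_resamples, N_CLASSES, N_CLASSES)
    diag = counts[:, np.arange(N_CLASSES), np.arange(N_CLASSES)].sum(axis=1)
    acc = diag / n
    row = counts.sum(axis=2)
    col = counts.sum(axis=1)
    p_e = (row * col).sum(axis=1) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (acc - p_e) / (1.0 - p_e)
    kappa = np.where(p_e >= 1.0 - 1e-15, np.where(acc >= 1.0 - 1e-15, 1.0, np.nan), kappa)
    return acc, kappa


@dataclasses.dataclass
class EvaluationReport:
    """Full test-set report (see module docstring)."""

    confusion: np.ndarray
    accuracy: float
    adjacent_fraction: float | None
    kappa: float
    bootstrap: dict  # per metric: {"mean": ..., "ci_low": ..., "ci_high": ...}
    p_accuracy: float | None
    n_resamples: int
    notes: list[str] = dataclasses.field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "adjacent_fraction": self.adjacent_fraction,
            "kappa": self.kappa,
            "bootstrap": self.bootstrap,
            "p_accuracy": self.p_accuracy,
            "n_resamples": self.n_resamples,
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def bootstrap_metrics(
    truth: np.ndarray,
    predicted: np.ndarray,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Bootstrap the (truth, predicted) pairs; mean and percentile 95% CI
    for accuracy and kappa, plus the raw accuracy resamples."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    rng = np.random.default_rng(seed)
    acc, kappa = _bootstrap_arrays(truth, predicted, n_resamples, rng)
    block = {}
    for name, arr in (("accuracy", acc), ("kappa", kappa)):
        finite = arr[np.isfinite(arr)]
        block[name] = {
            "mean": float(finite.mean()),
            "ci_low": float(np.percentile(finite, 2.5)),
            "ci_high": float(np.percentile(finite, 97.5)),
        }
    block["_accuracy_resamples"] = acc
    return block


def t_test_vs_chance(values: np.ndarray, null_value: float = 0.25) -> float:
    """One-sided one-sample Student's t-test p-value for mean > null_value."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values for a t-test")
    if np.all(values == values[0]) or np.std(values, ddof=1) == 0:
        raise ValueError(
            "values have zero variance; the t statistic is undefined — report "
            "the constant value separately instead of a p-value"
        )
    res = stats.ttest_1samp(values, null_value, alternative="greater")
    return float(res.pvalue)


def evaluate(
    truth: np.ndarray,
    predicted: np.ndarray,
    n_resamples: int = 10_000,
    seed: int | None = None,
) -> EvaluationReport:
    """Point metrics plus bootstrap uncertainty in one report."""
    conf = confusion_matrix(truth, predicted)
    acc = float(np.trace(conf) / conf.sum())
    block = bootstrap_metrics(truth, predicted, n_resamples=n_resamples, seed=seed)
    acc_resamples = block.pop("_accuracy_resamples")
    notes = []
    try:
        p_acc = t_test_vs_chance(acc_resamples, 0.25)
    except ValueError:
        p_acc = None
        notes.append(
            "bootstrap accuracies are constant "
            f"({acc_resamples[0]:.4f}); t-test against chance undefined"
        )
    return EvaluationReport(
        conf,
        acc,
        adjacent_fraction(conf),
        cohens_kappa(conf),
        block,
        p_acc,
        n_resamples,
        notes,
    )
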