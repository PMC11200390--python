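"""Shared pipeline fixtures.

The expensive end-to-end runs (simulate -> split -> PCA -> train -> predict
-> explain) are computed once per session and shared: ``separable_run`` is
a single run on the strongly separable fixture, ``separable_runs10`` the
ten-seed repetition used by the recovery and learning-sanity checks.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import bpexplain as bp


@dataclasses.dataclass
class PipelineRun:
    seed: int
    table: bp.FeatureTable
    assignment: bp.SplitAssignment
    pca: bp.PCAModel
    train_scores: bp.PCScores
    val_scores: bp.PCScores
    test_scores: bp.PCScores
    model: bp.ClassifierModel
    preds: bp.PredictionSet
    explanation: bp.ShapExplanation


def run_pipeline(
    fixture_name: str,
    seed: int,
    config: bp.PipelineConfig | None = None,
    background_size: int | None = 100,
    split_kwargs: dict | None = None,
    do_explain: bool = True,
) -> PipelineRun:
    config = config or bp.PipelineConfig()
    table = bp.make_fixture(fixture_name, seed=seed)
    assignment = bp.stratified_split(table, seed=seed, **(split_kwargs or {}))
    train_tab = table.subset(assignment.mask(table, "train"))
    pca = bp.fit_pca(train_tab, config.n_components)
    train_scores = bp.transform(pca, train_tab)
    val_scores = bp.transform(pca, table.subset(assignment.mask(table, "val")))
    test_scores = bp.transform(pca, table.subset(assignment.mask(table, "test")))
    model = bp.train(config, train_scores, val_scores, seed=seed)
    preds = bp.predict(model, test_scores)
    explanation = None
    if do_explain:
        explanation = bp.explain(
            model, train_scores, test_scores,
            background_size=background_size, seed=seed,
        )
    return PipelineRun(
        seed, table, assignment, pca, train_scores, val_scores, test_scores,
        model, preds, explanation,
    )


@pytest.fixture(scope="session")
def tiny_run() -> PipelineRun:
    """Fast full pipeline on the tiny fixture (seed 1 has all four classes)."""
    return run_pipeline(
        "tiny",
        seed=1,
        config=bp.PipelineConfig(epochs=30),
        background_size=None,
        split_kwargs=dict(min_fraction=0.0, tolerance=0.07),
    )


@pytest.fixture(scope="session")
def separable_run(separable_runs10) -> PipelineRun:
    return separable_runs10[0]


@pytest.fixture(scope="session")
def separable_runs10() -> list[PipelineRun]:
    """Ten independent end-to-end runs on the separable fixture (seeds 1-10)."""
    return [run_pipeline("separable", seed=s) for s in range(1, 11)]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240556)
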