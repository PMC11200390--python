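"""Evaluation metrics against frozen hand values and independent oracles."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import cohen_kappa_score

import bpexplain as bp


class TestConfusionMatrix:
    def test_identity_diagonal(self):
        conf = bp.confusion_matrix([1, 2, 3, 4], [1, 2, 3, 4])
        np.testing.assert_array_equal(conf, np.eye(4, dtype=int))

    def test_single_off_diagonal_cell(self):
        conf = bp.confusion_matrix([1, 1], [2, 2])
        expected = np.zeros((4, 4), int)
        expected[0, 1] = 2
        np.testing.assert_array_equal(conf, expected)

    def test_row_sums_are_truth_counts(self, rng):
        truth = rng.integers(1, 5, 200)
        pred = rng.integers(1, 5, 200)
        conf = bp.confusion_matrix(truth, pred)
        np.testing.assert_array_equal(
            conf.sum(axis=1), np.bincount(truth, minlength=5)[1:]
        )
        assert conf.sum() == 200

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bp.confusion_matrix([1, 5], [1, 1])


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert bp.cohens_kappa(np.diag([5, 3, 2, 7])) == pytest.approx(1.0)

    def test_chance_level_table(self):
        assert bp.cohens_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_frozen_hand_value(self):
        # p_o = 35/50 = 0.7; p_e = (25*30 + 25*20)/2500 = 0.5; kappa = 0.4
        assert bp.cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_degenerate_single_cell(self):
        # p_e = 1 only occurs when all mass sits in one diagonal cell
        assert bp.cohens_kappa([[10, 0], [0, 0]]) == 1.0
        # one-sided degeneracy is chance-level, not an error
        assert bp.cohens_kappa([[0, 10], [0, 0]]) == pytest.approx(0.0)
        with pytest.raises(ValueError, match="empty"):
            bp.cohens_kappa(np.zeros((4, 4)))

    def test_matches_sklearn_on_random_labels(self, rng):
        for _ in range(10):
            truth = rng.integers(1, 5, 300)
            pred = np.where(rng.random(300) < 0.6, truth, rng.integers(1, 5, 300))
            conf = bp.confusion_matrix(truth, pred)
            assert bp.cohens_kappa(conf) == pytest.approx(
                cohen_kappa_score(truth, pred), abs=1e-12
            )


class TestAdjacentFraction:
    def test_all_adjacent(self):
        conf = np.zeros((4, 4), int)
        conf[0, 0] = 10
        conf[0, 1] = 5
        assert bp.adjacent_fraction(conf) == 1.0

    def test_none_adjacent(self):
        conf = np.zeros((4, 4), int)
        conf[0, 0] = 10
        conf[0, 3] = 5
        assert bp.adjacent_fraction(conf) == 0.0

    def test_no_errors_undefined(self):
        assert bp.adjacent_fraction(np.diag([5, 5, 5, 5])) is None


class TestBootstrap:
    def test_all_correct_gives_degenerate_intervals(self):
        truth = np.repeat([1, 2, 3, 4], 10)
        block = bp.bootstrap_metrics(truth, truth, n_resamples=500, seed=0)
        assert block["accuracy"]["ci_low"] == block["accuracy"]["ci_high"] == 1.0
        assert block["kappa"]["ci_low"] == block["kappa"]["ci_high"] == 1.0

    def test_seeded_determinism(self, rng):
        truth = rng.integers(1, 5, 100)
        pred = rng.integers(1, 5, 100)
        a = bp.bootstrap_metrics(truth, pred, n_resamples=300, seed=7)
        b = bp.bootstrap_metrics(truth, pred, n_resamples=300, seed=7)
        assert a["accuracy"] == b["accuracy"] and a["kappa"] == b["kappa"]

    def test_ci_width_shrinks_with_sample_size(self):
        # matched predictions: ~75% accuracy at n=100 vs n=1000
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            widths = []
            for n in (100, 1000):
                truth = rng.integers(1, 5, n)
                flip = rng.random(n) < 0.25
                pred = np.where(flip, 1 + (truth % 4), truth)
                block = bp.bootstrap_metrics(truth, pred, n_resamples=1000,
                                             seed=seed)
                widths.append(
                    block["accuracy"]["ci_high"] - block["accuracy"]["ci_low"]
                )
            wins += widths[1] < widths[0]
        assert wins == 10

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            bp.bootstrap_metrics([1, 2], [1, 2], n_resamples=50)

    def test_kappa_consistency_full_vs_bootstrap_mean(self, rng):
        truth = rng.integers(1, 5, 400)
        pred = np.where(rng.random(400) < 0.7, truth, rng.integers(1, 5, 400))
        conf = bp.confusion_matrix(truth, pred)
        kappa = bp.cohens_kappa(conf)
        report = bp.evaluate(truth, pred, n_resamples=2000, seed=1)
        spread = (report.bootstrap["kappa"]["ci_high"]
                  - report.bootstrap["kappa"]["ci_low"]) / 3.92  # approx SE
        assert abs(report.bootstrap["kappa"]["mean"] - kappa) < 3 * spread


class TestTTest:
    def test_symmetric_values_give_half(self):
        rng = np.random.default_rng(0)
        jitter = rng.uniform(0.01, 0.05, 25)
        values = np.concatenate([0.25 + jitter, 0.25 - jitter])  # mean exactly .25
        assert bp.t_test_vs_chance(values) == pytest.approx(0.5)

    def test_far_above_chance(self):
        values = np.array([0.8, 0.9, 0.85, 0.88, 0.82])
        assert bp.t_test_vs_chance(values) < 0.001

    def test_matches_closed_form(self, rng):
        values = rng.normal(0.4, 0.1, 50)
        t = (values.mean() - 0.25) / (values.std(ddof=1) / np.sqrt(50))
        expected = float(stats.t.sf(t, df=49))
        assert bp.t_test_vs_chance(values) == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            bp.t_test_vs_chance(np.full(10, 0.3))


class TestEvaluateReport:
    def test_accuracy_consistent_with_direct_fraction(self, rng):
        truth = rng.integers(1, 5, 250)
        pred = np.where(rng.random(250) < 0.5, truth, rng.integers(1, 5, 250))
        report = bp.evaluate(truth, pred, n_resamples=200, seed=0)
        assert report.accuracy == pytest.approx(np.mean(truth == pred), abs=1e-12)
        assert report.confusion.sum() == 250

    def test_percentiles_bracket_point_estimate(self, rng):
        hits = 0
        for seed in range(20):
            truth = rng.integers(1, 5, 300)
            pred = np.where(rng.random(300) < 0.6, truth, rng.integers(1, 5, 300))
            rep = bp.evaluate(truth, pred, n_resamples=1000, seed=seed)
            hits += (
                rep.bootstrap["accuracy"]["ci_low"]
                <= rep.accuracy
                <= rep.bootstrap["accuracy"]["ci_high"]
            )
        assert hits >= 19

    def test_chance_predictions_kappa_ci_contains_zero(self):
        # class-imbalanced truth, independent predictions: no real agreement
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            truth = rng.choice([1, 2, 3, 4], p=[0.4, 0.25, 0.2, 0.15], size=400)
            pred = rng.choice([1, 2, 3, 4], p=[0.25] * 4, size=400)
            rep = bp.evaluate(truth, pred, n_resamples=1000, seed=seed)
            hits += (
                rep.bootstrap["kappa"]["ci_low"] <= 0.0
                <= rep.bootstrap["kappa"]["ci_high"]
            )
        assert hits >= 18

    def test_report_json_round_trip(self, tmp_path, rng):
        truth = rng.integers(1, 5, 80)
        pred = rng.integers(1, 5, 80)
        rep = bp.evaluate(truth, pred, n_resamples=200, seed=2)
        rep.to_json(tmp_path / "r.json")
        import json

        d = json.loads((tmp_path / "r.json").read_text())
        assert d["accuracy"] == rep.accuracy
        assert d["n_resamples"] == 200
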