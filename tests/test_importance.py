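"""Shapley-scaled loading vectors and their aggregation, vs brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import bpexplain as bp


# ---------------------------------------------------------------------------
# independent straight-line oracles (plain python, no shared code paths)

def _pct_linear(values, q):
    s = sorted(values)
    pos = (len(s) - 1) * q / 100.0
    lo = int(math.floor(pos))
    if lo + 1 >= len(s):
        return s[-1]
    return s[lo] + (s[lo + 1] - s[lo]) * (pos - lo)


def oracle_type_report(feature_names, scaled_coefs, pct):
    """Aggregate per-feature scaled coefficients exactly as described:
    length/orientation per feature, mean per terminal type, min-max rescale,
    percentile mask."""
    lengths, orients = {}, {}
    for name, row in zip(feature_names, scaled_coefs):
        ftype = name.rsplit("_", 1)[-1]
        lengths.setdefault(ftype, []).append(
            math.sqrt(sum(v * v for v in row))
        )
        orients.setdefault(ftype, []).append(sum(row))
    types = sorted(lengths)
    mean_len = {t: sum(lengths[t]) / len(lengths[t]) for t in types}
    mean_or = {t: sum(orients[t]) / len(orients[t]) for t in types}
    vals = [mean_len[t] for t in types]
    lo, hi = min(vals), max(vals)
    rescaled = {
        t: (mean_len[t] - lo) / (hi - lo) if hi > lo else 0.0 for t in types
    }
    thr = _pct_linear(vals, pct)
    mask = {t: mean_len[t] > thr for t in types}
    return types, mean_len, mean_or, rescaled, mask


def oracle_local(pca, alpha, pct):
    scaled = [
        [alpha[j] * pca.loadings[i, j] for j in range(len(alpha))]
        for i in range(len(pca.feature_names))
    ]
    return oracle_type_report(pca.feature_names, scaled, pct)


def oracle_global(pca, alphas, pct):
    n = len(alphas)
    scaled = [
        [
            sum(a[j] * pca.loadings[i, j] for a in alphas) / n
            for j in range(len(alphas[0]))
        ]
        for i in range(len(pca.feature_names))
    ]
    return oracle_type_report(pca.feature_names, scaled, pct)


def assert_report_matches_oracle(report, oracle, tol=1e-10):
    types, mean_len, mean_or, rescaled, mask = oracle
    frame = report.per_type.set_index("feature_type")
    assert sorted(frame.index) == types
    for t in types:
        assert frame.loc[t, "mean_scaled_length"] == pytest.approx(
            mean_len[t], abs=tol
        )
        assert frame.loc[t, "mean_orientation"] == pytest.approx(
            mean_or[t], abs=tol
        )
        assert frame.loc[t, "rescaled_length"] == pytest.approx(
            rescaled[t], abs=tol
        )
        assert bool(frame.loc[t, "above_percentile"]) == mask[t]


# ---------------------------------------------------------------------------
# elementary vector arithmetic

@pytest.mark.parametrize(
    "row, expected",
    [((3, 4, 0, 0), 5.0), ((0, 0, 0, 0), 0.0), ((1, 1, 1, 1), 2.0)],
)
def test_vector_length_examples(row, expected):
    assert bp.vector_length(np.array(row, float)) == pytest.approx(expected)


def test_shap_scaled_length_examples():
    row = np.array([3.0, 4.0, 0.0, 0.0])
    assert bp.shap_scaled_length(row, np.ones(4)) == pytest.approx(
        bp.vector_length(row)
    )
    assert bp.shap_scaled_length(row, np.zeros(4)) == 0.0
    assert bp.shap_scaled_length(row, np.array([2.0, 0, 0, 0])) == pytest.approx(6.0)


def test_orientation_examples():
    assert bp.orientation(np.array([1.0, -1, 2, -2]), np.ones(4)) == pytest.approx(0.0)
    assert bp.orientation(np.array([1.0, 0, 0, 0]),
                          np.array([-2.0, 0, 0, 0])) == pytest.approx(-2.0)
    row, alpha = np.array([0.3, -1.2, 0.7, 2.0]), np.array([1.1, 0.2, -0.4, 0.9])
    assert bp.orientation(row, -alpha) == pytest.approx(-bp.orientation(row, alpha))


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        bp.shap_scaled_length(np.ones(4), np.ones(3))
    with pytest.raises(ValueError):
        bp.orientation(np.ones(2), np.ones(4))


def test_arithmetic_matches_elementwise_oracle(rng):
    rows = rng.normal(size=(1000, 4))
    alphas = rng.normal(size=(1000, 4))
    for row, alpha in zip(rows, alphas):
        v = math.sqrt(sum(float(r) ** 2 for r in row))
        vs = math.sqrt(sum((float(a) * float(r)) ** 2 for a, r in zip(alpha, row)))
        o = sum(float(a) * float(r) for a, r in zip(alpha, row))
        assert bp.vector_length(row) == pytest.approx(v, abs=1e-12)
        assert bp.shap_scaled_length(row, alpha) == pytest.approx(vs, abs=1e-12)
        assert bp.orientation(row, alpha) == pytest.approx(o, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(
    row=hnp.arrays(float, 4, elements=st.floats(-10, 10)),
    alpha=hnp.arrays(float, 4, elements=st.floats(-10, 10)),
)
def test_scaled_length_bounded_by_max_alpha(row, alpha):
    bound = np.max(np.abs(alpha)) * bp.vector_length(row)
    assert bp.shap_scaled_length(row, alpha) <= bound + 1e-9


# ---------------------------------------------------------------------------
# report construction on hand-built models

def _fake_pca(names, loadings):
    return bp.PCAModel(
        list(names),
        np.zeros(len(names)),
        np.ones(len(names)),
        np.asarray(loadings, float),
        np.linspace(0.4, 0.1, np.asarray(loadings).shape[1]),
    )


def _fake_explanation(slice_ids, alphas_per_class):
    """alphas_per_class: (n_slices, 4, d)."""
    arr = np.asarray(alphas_per_class, float)
    return bp.ShapExplanation(
        np.array(slice_ids, dtype=object), np.full(4, 0.25), arr
    )


def test_single_component_alpha_ranking_matches_loading_magnitude(rng):
    names = [f.raw for f in bp.generate_feature_names(60)]
    loadings = rng.normal(size=(60, 4))
    pca = _fake_pca(names, loadings)
    alpha = np.array([2.5, 0.0, 0.0, 0.0])
    expl = _fake_explanation(["s1"], [[alpha, alpha, alpha, alpha]])
    report = bp.local_importance(pca, expl, "s1", 1)
    frame = report.per_type.set_index("feature_type")
    # ranking by mean scaled length == ranking by mean |phi_i1| within type
    types = list(frame.index)
    by_phi = {}
    for name, row in zip(names, loadings):
        by_phi.setdefault(name.rsplit("_", 1)[-1], []).append(abs(row[0]))
    phi_rank = sorted(types, key=lambda t: np.mean(by_phi[t]))
    len_rank = sorted(types, key=lambda t: frame.loc[t, "mean_scaled_length"])
    assert phi_rank == len_rank


def test_percentile_75_keeps_two_of_eight_types(rng):
    # 8 feature types with distinct lengths -> exactly 2 above the cut
    fclasses = ["firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm",
                "firstorder", "glcm"]
    names = [f"original_{c}_Type{i}" for i, c in enumerate(fclasses)]
    loadings = np.zeros((8, 4))
    for i in range(8):
        loadings[i, i % 4] = i + 1.0  # distinct row norms 1..8
    pca = _fake_pca(names, loadings)
    alpha = np.ones(4)
    expl = _fake_explanation(["s"], [[alpha] * 4])
    report = bp.local_importance(pca, expl, "s", 2, percentile_cut=75.0)
    assert int(report.per_type["above_percentile"].sum()) == 2


def test_local_report_matches_bruteforce_oracle(separable_run):
    run = separable_run
    for idx in (0, 5, 11):
        sid = str(run.preds.slice_id[idx])
        k = int(run.preds.predicted[idx])
        report = bp.local_importance(run.pca, run.explanation, sid, k)
        alpha = run.explanation.for_slice(sid)[k - 1]
        assert_report_matches_oracle(report, oracle_local(run.pca, alpha, 75.0))


def test_global_report_matches_bruteforce_oracle(separable_run):
    run = separable_run
    for k in sorted(set(run.preds.predicted.tolist())):
        report = bp.global_importance(
            run.pca, run.explanation, run.preds.predicted, k
        )
        mask = run.preds.predicted == k
        alphas = [run.explanation.shap_values[i, k - 1]
                  for i in np.nonzero(mask)[0]]
        assert_report_matches_oracle(report, oracle_global(run.pca, alphas, 75.0))


def test_global_of_single_slice_equals_local(tiny_run):
    run = tiny_run
    sid = str(run.preds.slice_id[0])
    k = int(run.preds.predicted[0])
    # predictions vector where only this slice carries class k
    fake_preds = np.full(len(run.preds.predicted), -1)
    fake_preds[0] = k
    fake_preds[fake_preds == -1] = (k % 4) + 1
    g = bp.global_importance(run.pca, run.explanation, fake_preds, k)
    loc = bp.local_importance(run.pca, run.explanation, sid, k)
    for col in ("mean_scaled_length", "rescaled_length", "mean_orientation"):
        np.testing.assert_allclose(
            g.per_type[col].to_numpy(), loc.per_type[col].to_numpy(), atol=1e-12
        )


def test_opposite_alphas_cancel(rng):
    names = [f.raw for f in bp.generate_feature_names(20)]
    pca = _fake_pca(names, rng.normal(size=(20, 4)))
    alpha = rng.normal(size=4)
    expl = _fake_explanation(
        ["a", "b"],
        [[alpha] * 4, [-alpha] * 4],
    )
    report = bp.global_importance(pca, expl, np.array([3, 3]), 3)
    np.testing.assert_allclose(
        report.per_type["mean_scaled_length"].to_numpy(), 0.0, atol=1e-12
    )


def test_mask_invariant_under_alpha_rescaling(rng):
    # scaling alpha by c > 0 is a monotone transform of type lengths
    names = [f.raw for f in bp.generate_feature_names(50)]
    pca = _fake_pca(names, rng.normal(size=(50, 4)))
    alpha = rng.normal(size=4)
    for c in (0.01, 3.7, 250.0):
        a = bp.local_importance(
            pca, _fake_explanation(["s"], [[alpha] * 4]), "s", 1
        )
        b = bp.local_importance(
            pca, _fake_explanation(["s"], [[c * alpha] * 4]), "s", 1
        )
        np.testing.assert_array_equal(
            a.per_type["above_percentile"].to_numpy(),
            b.per_type["above_percentile"].to_numpy(),
        )
        np.testing.assert_allclose(
            a.per_type["rescaled_length"].to_numpy(),
            b.per_type["rescaled_length"].to_numpy(),
            atol=1e-9,
        )


def test_above_percentile_fraction_bounded(separable_run):
    run = separable_run
    report = bp.global_importance(
        run.pca, run.explanation, run.preds.predicted,
        int(run.preds.predicted[0]),
    )
    n_types = len(report.per_type)
    frac = report.per_type["above_percentile"].mean()
    assert frac <= 0.25 + 1.0 / n_types


def test_empty_class_subset_rejected(tiny_run):
    preds = np.full(len(tiny_run.preds.predicted), 1)
    with pytest.raises(ValueError, match="no slices predicted"):
        bp.global_importance(tiny_run.pca, tiny_run.explanation, preds, 4)


def test_unknown_slice_rejected(tiny_run):
    with pytest.raises(KeyError):
        bp.local_importance(tiny_run.pca, tiny_run.explanation, "nope", 1)
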