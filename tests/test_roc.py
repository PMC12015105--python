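"""ROC machinery against brute-force and external oracles, plus invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import shumpanel as sp
from shumpanel.roc import ScoreSet, operating_point_at

finite_scores = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False), min_size=1, max_size=30
)


def brute_force_auc(pos, neg):
    """Pairwise double loop: 1 for a win, 1/2 for a tie."""
    total = 0.0
    for u in pos:
        for v in neg:
            total += 1.0 if u > v else (0.5 if u == v else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_trivial_cases():
    assert sp.empirical_auc([3, 4], [1, 2]) == 1.0
    assert sp.empirical_auc([1, 1, 1], [1, 1, 1]) == 0.5
    assert sp.empirical_auc([1, 2], [3, 4]) == 0.0


def test_auc_matches_brute_force_pairwise(rng):
    for _ in range(20):
        pos = rng.normal(0.5, 1, 15)
        neg = rng.normal(0.0, 1, 15)
        assert sp.empirical_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)


def test_auc_matches_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    pos = np.round(rng.normal(1, 1, 25), 1)  # rounding forces ties
    neg = np.round(rng.normal(0, 1, 30), 1)
    y = np.r_[np.ones(25), np.zeros(30)]
    assert sp.empirical_auc(pos, neg) == pytest.approx(
        roc_auc_score(y, np.r_[pos, neg]), abs=1e-12
    )


def test_empty_class_error_names_class():
    with pytest.raises(ValueError, match="positive"):
        sp.empirical_auc([], [1.0])
    with pytest.raises(ValueError, match="negative"):
        sp.empirical_auc([1.0], [])


@given(pos=finite_scores, neg=finite_scores)
@settings(max_examples=200, deadline=None)
def test_roc_trapezoid_equals_mann_whitney(pos, neg):
    curve = sp.roc_curve(pos, neg)
    assert curve.auc == pytest.approx(sp.empirical_auc(pos, neg), abs=1e-12)
    assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
    assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
    assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)
    assert np.all(np.diff(curve.thresholds) < 0)


@given(pos=finite_scores, neg=finite_scores)
@settings(max_examples=100, deadline=None)
def test_auc_class_swap_complement(pos, neg):
    assert sp.empirical_auc(pos, neg) + sp.empirical_auc(neg, pos) == pytest.approx(1.0)


def test_auc_invariant_under_monotone_transform(rng):
    pos, neg = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
    a = sp.empirical_auc(pos, neg)
    for f in (np.exp, np.arctan, lambda x: 3 * x + 7):
        assert sp.empirical_auc(f(pos), f(neg)) == pytest.approx(a, abs=1e-12)


def test_perfect_curve_passes_through_corner():
    curve = sp.roc_curve([2, 3], [0, 1])
    assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))


def test_youden_matches_exhaustive_threshold_search(rng):
    for _ in range(20):
        pos = np.round(rng.normal(0.8, 1, 10), 1)
        neg = np.round(rng.normal(0.0, 1, 10), 1)
        op = sp.youden_optimal(pos, neg)
        # exhaustive search over a fine grid spanning all observed scores
        grid = np.concatenate([[-np.inf, np.inf], np.sort(np.r_[pos, neg])[:-1] + 1e-9])
        best = max(
            (pos > t).mean() - (neg > t).mean() for t in grid
        )
        assert op.youden_j == pytest.approx(best, abs=1e-12)
        assert op.youden_j == op.tpr - op.fpr  # identity, exact


def test_youden_tie_breaks_toward_sensitivity():
    # two thresholds achieve J = 0.5; the lower one has higher TPR
    pos, neg = [1.0, 3.0], [0.0, 2.0]
    op = sp.youden_optimal(pos, neg)
    assert op.tpr == 1.0 and op.fpr == 0.5


def test_youden_perfect_classifier():
    op = sp.youden_optimal([2.0, 3.0], [0.0, 1.0])
    assert op.youden_j == 1.0 and op.mcc == 1.0


def test_youden_degenerate_single_value_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        op = sp.youden_optimal([1.0, 1.0], [1.0, 1.0])
    assert op.youden_j == 0.0


def test_mcc_values():
    assert sp.mcc_at(10, 0, 10, 0) == 1.0
    assert sp.mcc_at(10, 10, 0, 0) == 0.0  # all predicted positive -> convention 0
    assert sp.mcc_at(15, 1, 15, 1) == pytest.approx(0.875)
    assert sp.mcc_at(0, 0, 10, 10) == 0.0  # all predicted negative -> convention 0
    assert sp.mcc_at(0, 10, 0, 10) == -1.0  # every prediction wrong


def test_mcc_symmetric_under_joint_flip(rng):
    for _ in range(10):
        tp, fp, tn, fn = rng.integers(0, 30, 4)
        if tp + fp + tn + fn == 0:
            continue
        # swapping class labels and predictions together: TP<->TN, FP<->FN
        assert sp.mcc_at(tp, fp, tn, fn) == pytest.approx(sp.mcc_at(tn, fn, tp, fp))


def test_operating_point_counts_sum(rng):
    pos, neg = rng.normal(1, 1, 13), rng.normal(0, 1, 17)
    op = operating_point_at(pos, neg, 0.3)
    assert sum(op.confusion) == 30
    assert op.youden_j == op.tpr - op.fpr


# --- DeLong ---------------------------------------------------------------


def test_delong_identical_scores_p_one(rng):
    pos, neg = rng.normal(1, 1, 15), rng.normal(0, 1, 15)
    ss = ScoreSet(pos, neg)
    delta, z, p = sp.compare_auc(ss, ss, paired=True)
    assert delta == 0.0 and p == 1.0


def test_delong_matches_pROC_frozen_oracle():
    """Expected values computed once with R pROC::roc.test (method='delong',
    paired) and pROC::var on this exact fixture, then frozen."""
    rng = np.random.default_rng(42)
    pos = np.round(rng.normal(1, 1, 12), 3)
    neg = np.round(rng.normal(0, 1, 15), 3)
    pos2 = np.round(0.6 * pos + rng.normal(0, 0.8, 12), 3)
    neg2 = np.round(0.6 * neg + rng.normal(0, 0.8, 15), 3)
    delta, z, p = sp.compare_auc(ScoreSet(pos, neg), ScoreSet(pos2, neg2), paired=True)
    assert z == pytest.approx(1.803576, abs=1e-5)
    assert p == pytest.approx(0.0712978, abs=1e-5)
    assert sp.delong_auc_variance(pos, neg) == pytest.approx(0.01008698, abs=1e-7)


def test_delong_paired_mismatched_ids_rejected(rng):
    pos, neg = rng.normal(1, 1, 5), rng.normal(0, 1, 5)
    a = ScoreSet(pos, neg, positive_ids=("a", "b", "c", "d", "e"))
    b = ScoreSet(pos + 0.1, neg, positive_ids=("a", "b", "c", "d", "X"))
    with pytest.raises(ValueError, match="sample ids"):
        sp.compare_auc(a, b, paired=True)


def test_delong_variance_close_to_bootstrap(rng):
    pos, neg = rng.normal(1.0, 1, 20), rng.normal(0, 1, 20)
    vd = sp.delong_auc_variance(pos, neg)
    vb = sp.bootstrap_auc_variance(pos, neg, n_boot=2000, seed=1)
    assert vd == pytest.approx(vb, rel=0.15)


def test_ev_vs_serum_attenuation_detected_paired():
    """EV panel (strong marker) vs matched attenuated serum panel: paired
    DeLong flags the difference at p < 1e-4 in most replicates."""
    spec = sp.MarkerSpec(name="M0", fold_change=sp.calibrate_fold_from_auc(0.95, 0.6),
                         cv=0.6, serum_attenuation=0.2)
    hits = 0
    n_rep = 10
    for seed in range(n_rep):
        d = sp.PanelDesign(markers=[spec], n_per_class={"PS": 44, "PR": 44}, seed=seed)
        ev, serum = sp.generate_paired_panels(d)
        a = sp.marker_scores(ev, "M0")
        b = sp.marker_scores(serum, "M0")
        _, _, p = sp.compare_auc(a, b, paired=True)
        hits += p < 1e-4
    assert hits > n_rep / 2


# --- correlation ----------------------------------------------------------


def test_correlation_matrix_matches_naive_loop(rng):
    from conftest import make_panel

    X = rng.normal(size=(10, 4))
    panel = make_panel(X[:5], X[5:], ["a", "b", "c", "d"])
    got = sp.correlation_matrix(panel).to_numpy()
    naive = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            xi, xj = X[:, i], X[:, j]
            naive[i, j] = ((xi - xi.mean()) * (xj - xj.mean())).sum() / np.sqrt(
                ((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum()
            )
    assert np.allclose(got, naive, atol=1e-12)
    assert np.allclose(np.diag(got), 1.0)
    assert np.allclose(got, got.T)


def test_correlation_zero_variance_marker_reported_missing(rng):
    from conftest import make_panel

    X = rng.normal(size=(8, 2))
    X[:, 1] = 5.0
    panel = make_panel(X[:4], X[4:], ["a", "flat"])
    got = sp.correlation_matrix(panel)
    assert got.loc["a", "flat"] != got.loc["a", "flat"]  # NaN
    assert got.loc["a", "a"] == 1.0


def test_plot_roc_writes_figure(tmp_path, rng):
    curves = {"m": sp.roc_curve(rng.normal(1, 1, 10), rng.normal(0, 1, 10))}
    from shumpanel.roc import plot_roc

    out = tmp_path / "roc.png"
    plot_roc(curves, out)
    assert out.stat().st_size > 0


def test_negated_marker_perfectly_anticorrelated(rng):
    from conftest import make_panel

    x = rng.normal(size=10)
    panel = make_panel(
        np.column_stack([x, -x])[:5], np.column_stack([x, -x])[5:], ["m", "neg"]
    )
    assert sp.correlation_matrix(panel).loc["m", "neg"] == pytest.approx(-1.0)
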