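"""Diagnostic statistics: oracles for confusion/ROC/AUC, Bayes PPV/NPV,
detection tables, permutation importance."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import roc_auc_score

import spectriage as sp
from spectriage.evaluate import (as_percent, confusion, detection_table,
                                 fold_improvement, make_bins, npv,
                                 permutation_importance, ppv, roc_curve,
                                 round_half_away)


def pairwise_auc_oracle(scores, labels):
    """Brute-force Mann-Whitney pair probability with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_confusion_matches_brute_force_tally():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(4, 40)
        calls = rng.integers(0, 2, n)
        labels = rng.integers(0, 2, n)
        c = confusion(calls, labels)
        tp = sum(1 for a, b in zip(calls, labels) if a == 1 and b == 1)
        fp = sum(1 for a, b in zip(calls, labels) if a == 1 and b == 0)
        tn = sum(1 for a, b in zip(calls, labels) if a == 0 and b == 0)
        fn = sum(1 for a, b in zip(calls, labels) if a == 0 and b == 1)
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)
        assert c.tp + c.fn == labels.sum()


def test_confusion_all_correct_toy():
    c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)


def test_auc_matches_pairwise_oracle_random_instances():
    """Trapezoidal threshold-sweep AUC equals the Mann-Whitney oracle on 200
    random small instances (with ties)."""
    rng = np.random.default_rng(1)
    for _ in range(200):
        n = int(rng.integers(4, 25))
        # coarse scores force ties
        scores = rng.integers(0, 6, n) / 5.0
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        res = roc_curve(scores, labels)
        assert res.auc == pytest.approx(pairwise_auc_oracle(scores, labels),
                                        abs=1e-12)


def test_auc_agrees_with_sklearn():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=300)
    labels = (scores + rng.normal(size=300) > 0).astype(int)
    assert roc_curve(scores, labels).auc == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


def test_auc_separated_and_null():
    assert roc_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]).auc == 1.0
    rng = np.random.default_rng(3)
    scores = rng.normal(size=4000)
    labels = rng.integers(0, 2, 4000)
    assert abs(roc_curve(scores, labels).auc - 0.5) < 0.03


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    scores = rng.normal(size=100)
    labels = rng.integers(0, 2, 100)
    labels[0], labels[1] = 0, 1
    a1 = roc_curve(scores, labels).auc
    a2 = roc_curve(np.exp(3 * scores) - 2, labels).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_roc_points_sorted_and_one_class_error():
    res = roc_curve([0.2, 0.8, 0.5], [1, 0, 1])
    thresholds = [p.threshold for p in res.points]
    assert thresholds == sorted(thresholds)
    with pytest.raises(ValueError, match="both classes"):
        roc_curve([0.1, 0.2], [1, 1])


def test_ppv_npv_published_operating_points():
    """Bayes formulas reproduce the published predictive values exactly."""
    assert as_percent(ppv(0.96, 0.45, 0.078)) == 12.9
    assert as_percent(npv(0.96, 0.45, 0.078)) == 99.3
    assert as_percent(ppv(0.47, 0.90, 0.078)) == 28.4
    assert as_percent(npv(0.47, 0.90, 0.078)) == 95.3
    assert ppv(0.5, 0.5, 0.3) == pytest.approx(0.3)   # uninformative test
    assert npv(1.0, 0.7, 0.2) == 1.0                  # no false negatives


def test_ppv_npv_against_expected_confusion_oracle():
    """PPV/NPV equal tp/(tp+fp) and tn/(tn+fn) built from expected confusion
    counts at N=1e6, for 1000 random (sens, spec, prev) triples."""
    rng = np.random.default_rng(5)
    N = 10**6
    for _ in range(1000):
        sens, spec = rng.uniform(0.05, 0.99, 2)
        prev = rng.uniform(0.01, 0.99)
        tp = N * prev * sens
        fn = N * prev - tp
        tn = N * (1 - prev) * spec
        fp = N * (1 - prev) - tn
        assert ppv(sens, spec, prev) == pytest.approx(tp / (tp + fp), rel=1e-9)
        assert npv(sens, spec, prev) == pytest.approx(tn / (tn + fn), rel=1e-9)


@given(st.floats(0.05, 0.99), st.floats(0.05, 0.99),
       st.floats(0.01, 0.5), st.floats(0.01, 0.45))
def test_ppv_monotone_increasing_npv_decreasing_in_prevalence(
        sens, spec, prev, delta):
    assert ppv(sens, spec, prev + delta) >= ppv(sens, spec, prev)
    assert npv(sens, spec, prev + delta) <= npv(sens, spec, prev)


def test_fold_improvement():
    assert fold_improvement(0.129, 0.001) == pytest.approx(129.0)
    assert fold_improvement(0.129, 0.001) >= 100.0
    assert fold_improvement(0.42, 0.42) == 1.0
    assert fold_improvement(0.129, 0.029) == pytest.approx(4.45, abs=0.005)
    with pytest.raises(ValueError):
        fold_improvement(0.1, 0.0)


def test_round_half_away_from_zero():
    assert round_half_away(12.85, 1) == 12.9
    assert round_half_away(-12.85, 1) == -12.9
    assert round_half_away(14.2, 0) == 14.0
    assert as_percent(0.128664) == 12.9


def test_detection_table_fixture():
    """20/20 GBM and 9/10 meningioma correct -> rates 100% and 90%; TOTAL row
    consistent with the per-row sums."""
    subtypes = ["GBM"] * 20 + ["Meningioma"] * 10 + ["non-cancer"] * 30
    labels = [1] * 30 + [0] * 30
    calls = [1] * 20 + [1] * 9 + [0] + [0] * 30
    table = detection_table(calls, labels, subtypes).set_index("subtype")
    assert table.loc["GBM", "detection_rate"] == 100.0
    assert table.loc["Meningioma", "detection_rate"] == 90.0
    assert table.loc["TOTAL", "actual"] == 30
    assert table.loc["TOTAL", "identified"] == 29
    body = table.drop(index="TOTAL")
    assert body["actual"].sum() == table.loc["TOTAL", "actual"]
    assert body["identified"].sum() == table.loc["TOTAL", "identified"]


def test_permutation_importance_null_and_constant_bins(small_cohort,
                                                       small_features):
    """Labels shuffled -> importances within permutation noise of zero; a bin
    made constant has importance exactly zero."""
    _, records = small_cohort
    fm = small_features
    mdl = sp.fit_pls(fm.X, (fm.labels == "positive").astype(int), 4)
    bins = make_bins(1800, 1000, 100)

    import copy
    shuffled = copy.deepcopy(records)
    rng = np.random.default_rng(6)
    labels = [r.label for r in shuffled]
    rng.shuffle(labels)
    for r, lab in zip(shuffled, labels):
        r.label = lab
    fm2 = sp.preprocess_cohort(shuffled, sp.PreprocessConfig())
    mdl2 = sp.fit_pls(fm2.X, (fm2.labels == "positive").astype(int), 2)
    imp_null = permutation_importance(mdl2, shuffled, fm2, 0.5, bins,
                                      n_repeats=3, seed=0)
    assert np.all(np.abs(imp_null.importance) < 0.25)

    # constant bin: zero the first 100-wide bin everywhere
    fm3 = copy.deepcopy(fm)
    mask = fm3.wavenumbers > 1700
    fm3.X[:, mask] = 0.123
    mdl3 = sp.fit_pls(fm3.X, (fm3.labels == "positive").astype(int), 2)
    imp = permutation_importance(mdl3, records, fm3, 0.5, bins,
                                 n_repeats=2, seed=0)
    assert imp.importance.iloc[0] == 0.0


def test_permutation_importance_requires_partition(small_cohort,
                                                   small_features):
    _, records = small_cohort
    fm = small_features
    mdl = sp.fit_pls(fm.X, (fm.labels == "positive").astype(int), 2)
    with pytest.raises(ValueError, match="partition"):
        permutation_importance(mdl, records, fm, 0.5,
                               [(1800.0, 1500.0)], n_repeats=1)
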