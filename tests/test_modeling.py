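"""Selection, training, evaluation, ensembles and the DeLong test."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from thyradiomics.modeling import (
    EnsembleRule,
    FittedModel,
    ModelSpec,
    build_estimator,
    default_model_specs,
    delong_auc_variance,
    delong_test,
    ensemble_predict,
    evaluate,
    sequential_forward_select,
    train,
    youden_threshold,
)
from thyradiomics.modeling import _cv_auc


def _toy_table(rng, n=60, n_noise=5):
    y = np.array([1] * (n // 3) + [0] * (n - n // 3))
    sep = y * 4.0 + rng.normal(0, 0.5, n)  # near-perfect separator
    cols = {"separator": sep}
    for i in range(n_noise):
        cols[f"noise{i}"] = rng.normal(0, 1, n)
    return pd.DataFrame(cols), y


# ---------------------------------------------------------------------------
# Model specs


def test_default_zoo_covers_ten_architectures():
    specs = default_model_specs()
    archs = {s.architecture for s in specs}
    assert len(archs) == 10
    balanced = {s.architecture for s in specs if s.class_weight == "balanced"}
    assert balanced == {"logistic", "svc", "decision_tree", "random_forest"}


def test_balanced_weights_rejected_where_unsupported():
    with pytest.raises(ValueError):
        ModelSpec("knn", class_weight="balanced")


def test_balanced_weight_ratio_matches_class_frequencies():
    # classes 10:28 -> balanced weights inversely proportional, ratio 2.8
    from sklearn.utils.class_weight import compute_class_weight

    y = np.array([1] * 10 + [0] * 28)
    w = compute_class_weight("balanced", classes=np.array([0, 1]), y=y)
    assert w[1] / w[0] == pytest.approx(2.8)
    est = build_estimator(ModelSpec("logistic", class_weight="balanced"))
    assert est.class_weight == "balanced"


# ---------------------------------------------------------------------------
# Sequential forward selection


def test_sfs_recovers_planted_separator():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        table, y = _toy_table(rng)
        subset = sequential_forward_select(ModelSpec("logistic"), table, y, seed=seed)
        hits += "separator" in subset
    assert hits >= 19


def test_sfs_pair_matches_exhaustive_search():
    rng = np.random.default_rng(3)
    table, y = _toy_table(rng, n=40, n_noise=2)
    spec = ModelSpec("logistic")
    subset, trace = sequential_forward_select(
        spec, table, y, k_min=2, k_max=2, seed=0, return_trace=True
    )
    # greedy step 1: the best single feature by the same CV criterion
    est = build_estimator(spec, 0)
    singles = {
        f: _cv_auc(est, table[[f]].to_numpy(), y, seed=0) for f in table.columns
    }
    best_single = max(sorted(singles), key=lambda f: singles[f])
    assert trace[0][0] == (best_single,)
    # greedy step 2: best partner of that feature
    pairs = {
        f: _cv_auc(est, table[[best_single, f]].to_numpy(), y, seed=0)
        for f in table.columns
        if f != best_single
    }
    best_pair = max(sorted(pairs), key=lambda f: pairs[f])
    assert set(subset) == {best_single, best_pair}


def test_sfs_deterministic_given_seed():
    rng = np.random.default_rng(5)
    table, y = _toy_table(rng, n=40)
    a = sequential_forward_select(ModelSpec("logistic"), table, y, seed=7)
    b = sequential_forward_select(ModelSpec("logistic"), table, y, seed=7)
    assert a == b


def test_training_separable_data_perfectly():
    table = pd.DataFrame({"x": [0.0, 0.1, 0.2, 5.0, 5.1, 5.2], "z": [1.0] * 6})
    y = np.array([0, 0, 0, 1, 1, 1])
    model = train(ModelSpec("logistic"), table, y)
    assert (model.predict(table.to_numpy()) == y).all()


def test_refit_gives_identical_predictions():
    rng = np.random.default_rng(6)
    table, y = _toy_table(rng, n=40)
    m1 = train(ModelSpec("mlp"), table, y, seed=3)
    m2 = train(ModelSpec("mlp"), table, y, seed=3)
    assert np.array_equal(
        m1.predict_proba(table.to_numpy()), m2.predict_proba(table.to_numpy())
    )


# ---------------------------------------------------------------------------
# Evaluation


def test_perfect_ranking():
    rep = evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert rep.auc == 1.0
    assert rep.sensitivity == 1.0
    assert rep.specificity == 1.0
    assert rep.f_score == 1.0


def test_hand_confusion_matrix():
    rep = evaluate([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
    assert rep.auc == pytest.approx(0.75)
    assert rep.sensitivity == 0.5
    assert rep.specificity == 0.5
    assert rep.accuracy == 0.5
    assert rep.f_score == 0.5


def test_auc_equals_mann_whitney_statistic():
    rng = np.random.default_rng(9)
    for _ in range(10):
        y = rng.integers(0, 2, 40)
        if y.sum() in (0, 40):
            continue
        s = rng.normal(0, 1, 40) + y
        rep = evaluate(s, y)
        u = mannwhitneyu(s[y == 1], s[y == 0]).statistic
        assert rep.auc == pytest.approx(u / (y.sum() * (40 - y.sum())))


def test_metrics_are_probabilities():
    rng = np.random.default_rng(10)
    y = np.array([1] * 10 + [0] * 20)
    rep = evaluate(rng.random(30), y)
    for v in (rep.auc, rep.sensitivity, rep.specificity, rep.accuracy, rep.f_score):
        assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# Ensembles


class _ConstModel:
    def __init__(self, p):
        self.p = np.asarray(p, dtype=float)

    def predict_proba(self, x):
        return np.column_stack([1 - self.p, self.p])


def _fitted(p, threshold=0.5):
    n = len(p)
    return FittedModel(
        ModelSpec("logistic"), _ConstModel(p), features=["f"], threshold=threshold
    )


def test_and_with_itself_is_identity():
    table = pd.DataFrame({"f": np.zeros(4)})
    m = _fitted([0.9, 0.2, 0.6, 0.4])
    single = m.predict(table)
    both = ensemble_predict(EnsembleRule("AND"), [m, m], table)
    assert np.array_equal(single, both)


def test_and_or_truth_table():
    table = pd.DataFrame({"f": np.zeros(1)})
    a, b = _fitted([0.9]), _fitted([0.1])
    assert ensemble_predict(EnsembleRule("AND"), [a, b], table).tolist() == [0]
    assert ensemble_predict(EnsembleRule("OR"), [a, b], table).tolist() == [1]


def test_and_positive_subset_of_or_positive():
    rng = np.random.default_rng(11)
    table = pd.DataFrame({"f": np.zeros(50)})
    a, b = _fitted(rng.random(50)), _fitted(rng.random(50))
    and_pred = ensemble_predict(EnsembleRule("AND"), [a, b], table)
    or_pred = ensemble_predict(EnsembleRule("OR"), [a, b], table)
    assert np.all(and_pred <= or_pred)


def test_youden_threshold_recovers_constructed_cut():
    # below 0.35 only negatives, above only positives -> optimal cut there
    scores = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1])
    thr = youden_threshold(scores, labels)
    assert 0.3 < thr <= 0.4


# ---------------------------------------------------------------------------
# DeLong


def test_identical_scores_null_result():
    y = [1, 1, 0, 0, 1, 0]
    s = [0.9, 0.7, 0.4, 0.2, 0.6, 0.3]
    dauc, se, p = delong_test(s, s, y)
    assert dauc == 0.0
    assert p == 1.0


def test_delong_auc_consistent_with_evaluate():
    rng = np.random.default_rng(12)
    y = np.array([1] * 12 + [0] * 18)
    a = rng.normal(0, 1, 30) + y
    b = rng.normal(0, 1, 30) + 0.5 * y
    dauc, _, _ = delong_test(a, b, y)
    assert dauc == pytest.approx(evaluate(a, y).auc - evaluate(b, y).auc)


def test_delong_p_agrees_with_permutation_reference():
    # sign-flip permutation of the paired model assignment as oracle
    rng = np.random.default_rng(13)
    n = 30
    y = np.array([1] * 12 + [0] * 18)
    a = 0.7 * y + rng.normal(0, 0.6, n)
    b = 0.4 * y + rng.normal(0, 0.6, n)
    dauc, se, p = delong_test(a, b, y)

    def auc_diff(x1, x2):
        return evaluate(x1, y).auc - evaluate(x2, y).auc

    observed = abs(auc_diff(a, b))
    count = 0
    n_perm = 2000
    for _ in range(n_perm):
        flip = rng.random(n) < 0.5
        aa = np.where(flip, b, a)
        bb = np.where(flip, a, b)
        count += abs(auc_diff(aa, bb)) >= observed - 1e-12
    p_perm = count / n_perm
    assert p == pytest.approx(p_perm, abs=0.1)


def test_delong_variance_positive_and_small_for_large_n():
    rng = np.random.default_rng(14)
    y = np.array([1] * 100 + [0] * 200)
    s = rng.normal(0, 1, 300) + 1.2 * y
    v = delong_auc_variance(s, y)
    assert 0 < v < 0.01
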