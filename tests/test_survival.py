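"""Feature-selection cascade and LTS/STS classification."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from imctme.survival import (
    SelectionTrace,
    decorrelate,
    evaluate,
    loocv_select,
    minmax_scale,
    rfe_rank,
    run_cascade,
    spearman_filter,
    stratified_split,
)


def _labels(n_lts, n_sts):
    ids = [f"L{i}" for i in range(n_lts)] + [f"S{i}" for i in range(n_sts)]
    return pd.Index(ids), pd.Series(["LTS"] * n_lts + ["STS"] * n_sts, index=ids)


def test_split_21_20_gives_balanced_train_and_ratio_1_25():
    ids, labels = _labels(21, 20)
    train, test = stratified_split(ids, labels, seed=0)
    train_counts = labels.loc[train].value_counts()
    assert train_counts["LTS"] == 16 and train_counts["STS"] == 16
    test_counts = labels.loc[test].value_counts()
    assert test_counts["LTS"] == 5 and test_counts["STS"] == 4
    assert test_counts["LTS"] / test_counts["STS"] == pytest.approx(1.25)


def test_split_balanced_cohort_and_determinism():
    ids, labels = _labels(10, 10)
    train, test = stratified_split(ids, labels, seed=3)
    counts = labels.loc[train].value_counts()
    assert counts["LTS"] == 8 and counts["STS"] == 8
    assert len(test) == 4
    train2, test2 = stratified_split(ids, labels, seed=3)
    assert train == train2 and test == test2


def test_split_rejects_tiny_class():
    ids, labels = _labels(1, 10)
    with pytest.raises(ValueError, match="too small"):
        stratified_split(ids, labels, train_frac=0.5)


def test_spearman_filter_keeps_signal_drops_constant():
    ids, labels = _labels(16, 16)
    y = (labels == "LTS").astype(float)
    X = pd.DataFrame(
        {
            "same": y,                     # r = 1
            "anti": -y,                    # r = -1, kept by absolute value
            "flat": np.ones(len(ids)),     # undefined, dropped
        },
        index=ids,
    )
    trace = SelectionTrace()
    kept = spearman_filter(X, y, trace=trace)
    assert kept == ["same", "anti"]
    assert "Spearman undefined" in trace.stages[0]["dropped"]["flat"]


def test_spearman_filter_null_drop_rate_matches_simulated_null():
    """The drop rate of independent noise at n = 32 matches the null
    Spearman distribution (P(|r| <= 0.2) ~ 0.73 against a 16/16 binary
    target), estimated here by an independent rank-correlation oracle."""
    ids, labels = _labels(16, 16)
    y = (labels == "LTS").astype(float)
    # oracle: direct Monte-Carlo of Spearman under independence
    rng = np.random.default_rng(99)
    yv = y.to_numpy()
    oracle_draws = 4000
    r_null = np.empty(oracle_draws)
    for i in range(oracle_draws):
        x = rng.standard_normal(32)
        r_null[i] = scipy.stats.spearmanr(x, yv).statistic
    oracle_rate = float((np.abs(r_null) <= 0.2).mean())

    n_features = 400
    rng2 = np.random.default_rng(7)
    X = pd.DataFrame(
        rng2.standard_normal((32, n_features)),
        index=ids,
        columns=[f"noise{i}" for i in range(n_features)],
    )
    kept = spearman_filter(X, y)
    observed_rate = 1 - len(kept) / n_features
    se = np.sqrt(oracle_rate * (1 - oracle_rate) / n_features)
    assert abs(observed_rate - oracle_rate) < 4 * se


def test_decorrelate_duplicates_and_greedy_rule():
    rng = np.random.default_rng(0)
    ids = pd.Index([f"s{i}" for i in range(40)])
    y = pd.Series(np.r_[np.ones(20), np.zeros(20)], index=ids)
    a = y.to_numpy().copy().astype(float)  # r vs target = 1 exactly
    b = a.copy()
    b[0], b[-1] = b[-1], b[0]  # one discordant swap: still ~a, weaker vs y
    X = pd.DataFrame({"A": a, "B": b, "C": rng.standard_normal(40)}, index=ids)
    trace = SelectionTrace()
    kept = decorrelate(X, y, trace=trace)
    assert set(kept) == {"A", "C"}
    assert "A" in trace.stages[0]["dropped"]["B"]

    # identical features: exactly one survives
    X2 = pd.DataFrame({"x": a, "y": a}, index=ids)
    assert len(decorrelate(X2, y)) == 1

    # all pairwise |r| < threshold: no-op
    X3 = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("pqr"), index=ids)
    assert len(decorrelate(X3, y)) == 3


def test_minmax_scaling_contract():
    train = pd.DataFrame({"f": [2.0, 4.0, 6.0], "const": [1.0, 1.0, 1.0]})
    test = pd.DataFrame({"f": [0.0, 8.0], "const": [3.0, 1.0]})
    tr, te = minmax_scale(train, test)
    np.testing.assert_allclose(tr["f"], [0.0, 0.5, 1.0])
    np.testing.assert_allclose(tr["const"], 0.0)
    np.testing.assert_allclose(te["f"], [0.0, 1.0])  # clipped


def test_rfe_ranks_planted_signal_first():
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        y = pd.Series(np.r_[np.ones(16), np.zeros(16)])
        X = pd.DataFrame(rng.standard_normal((32, 6)), columns=[f"n{i}" for i in range(6)])
        X["signal"] = y + rng.normal(0, 0.05, 32)  # near-perfect separator
        X, _ = minmax_scale(X)
        hits += rfe_rank(X, y)[0] == "signal"
    assert hits >= 0.95 * n_seeds


def test_rfe_single_feature_and_duplicated_signal():
    y = pd.Series(np.r_[np.ones(10), np.zeros(10)])
    X = pd.DataFrame({"only": np.r_[np.ones(10), np.zeros(10)]})
    assert rfe_rank(X, y) == ["only"]

    rng = np.random.default_rng(1)
    sig = y + rng.normal(0, 0.05, 20)
    X2 = pd.DataFrame({"sig_a": sig, "sig_b": sig, "noise": rng.standard_normal(20)})
    ranking = rfe_rank(X2, y)
    # coefficient mass splits across the duplicated pair: one of them ranks
    # behind the other
    assert {"sig_a", "sig_b"} & {ranking[0]}


def test_loocv_selects_smallest_perfect_model():
    rng = np.random.default_rng(2)
    y = pd.Series(np.r_[np.ones(12), np.zeros(12)])
    X = pd.DataFrame(
        {
            "perfect": y.to_numpy() * 1.0,
            "noise1": rng.standard_normal(24),
            "noise2": rng.standard_normal(24),
        }
    )
    ranking = rfe_rank(X, y)
    assert ranking[0] == "perfect"
    train_acc, cv_acc, chosen = loocv_select(X, y, ranking)
    assert cv_acc[chosen] == 1.0
    assert chosen == min(n for n, acc in cv_acc.items() if acc == 1.0)


def test_loocv_full_size_matches_manual_leave_one_out():
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(3)
    y = pd.Series(rng.integers(0, 2, 20))
    X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
    _, cv_acc, _ = loocv_select(X, y, list("abc"))
    correct = 0
    for i in range(20):
        tr = [j for j in range(20) if j != i]
        model = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        model.fit(X.iloc[tr].to_numpy(), y.iloc[tr].to_numpy())
        correct += model.predict(X.iloc[[i]].to_numpy())[0] == y.iloc[i]
    assert cv_acc[3] == pytest.approx(correct / 20)


class _StubModel:
    """Fixed predictions/probabilities for metric arithmetic checks."""

    classes_ = np.array([0, 1])

    def __init__(self, pred, prob):
        self._pred = np.asarray(pred)
        self._prob = np.asarray(prob)

    def predict(self, X):
        return self._pred

    def predict_proba(self, X):
        return np.column_stack([1 - self._prob, self._prob])


def test_evaluate_confusion_matrix_arithmetic():
    # TP=5 FN=0 TN=3 FP=1 -> accuracy 8/9, sensitivity 1, specificity 0.75
    y = pd.Series([1] * 5 + [0] * 4)
    pred = [1] * 5 + [0, 0, 0, 1]
    prob = [0.9] * 5 + [0.1, 0.2, 0.3, 0.8]
    X = pd.DataFrame(np.zeros((9, 1)))
    out = evaluate(_StubModel(pred, prob), X, y)
    assert out["accuracy"] == pytest.approx(8 / 9)
    assert out["sensitivity"] == pytest.approx(1.0)
    assert out["specificity"] == pytest.approx(0.75)


def test_evaluate_perfect_and_constant_probabilities():
    y = pd.Series([1, 1, 0, 0])
    X = pd.DataFrame(np.zeros((4, 1)))
    perfect = evaluate(_StubModel([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2]), X, y)
    assert perfect["auc"] == pytest.approx(1.0)
    assert perfect["accuracy"] == pytest.approx(1.0)
    constant = evaluate(_StubModel([1, 1, 1, 1], [0.5, 0.5, 0.5, 0.5]), X, y)
    assert constant["auc"] == pytest.approx(0.5)  # midrank ROC convention


def test_interaction_family_prefilter_requires_prognostic_subtype_and_significance():
    from imctme.survival import interaction_family

    comparison = pd.DataFrame(
        {"significant": [True, True, False]},
        index=["AvgC_CD8_4__tu_1", "AvgC_s_1__ma_1", "AvgC_CD8_4__tu_2"],
    )
    cols = ["AvgC_CD8_4__tu_1", "AvgC_s_1__ma_1", "AvgC_CD8_4__tu_2", "AvgC_ma_1__s_1"]
    kept = interaction_family(cols, ["CD8_4"], comparison)
    # needs a prognostic anchor/partner AND a BH-significant comparison
    assert kept == ["AvgC_CD8_4__tu_1"]


def test_cascade_trace_composes_and_reproduces_final_set(small_cohort):
    from imctme.spatial import sample_feature_matrix
    from imctme.synth import cohort_cell_table, cohort_survival_table

    tissue, _, cohort = small_cohort
    cells = cohort_cell_table(cohort)
    surv = cohort_survival_table(cohort).set_index("sample_id")
    feats = sample_feature_matrix(cells, tissue.tumor_subtypes, tissue.image_shape)
    feats = feats.join(surv["age"])
    report, trace = run_cascade(feats, surv["class"], seed=0)
    # stages chain: out-set of stage i = in-set of stage i+1
    for earlier, later in zip(trace.stages, trace.stages[1:]):
        assert earlier["out"] == later["in"]
    # replaying the recorded drops reproduces the final feature pool
    replayed = [f for f in trace.stages[0]["in"]
                if not any(f in st["dropped"] for st in trace.stages)]
    assert replayed == trace.final_features()
    assert set(report.chosen_features) <= set(trace.final_features())
    assert report.chosen_size == len(report.chosen_features)
    assert report.loocv_accuracy[report.chosen_size] == max(report.loocv_accuracy.values())
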