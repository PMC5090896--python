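"""Classification protocol: metrics vs brute-force oracles, dedup, splits,
tuned models."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from chimerabench.classify import (
    METHODS,
    aggregate_metrics,
    auc,
    confusion,
    deduplicate,
    evaluate,
    feature_selection_report,
    kappa,
    make_runs,
    run_protocol,
    train_model,
)
from chimerabench.profiler import FEATURES8


def test_kappa_hand_computation():
    # po = 0.85, pe = 0.5 -> kappa = 0.70
    assert kappa(tp=40, fp=5, fn=10, tn=45) == pytest.approx(0.70)
    tp, fp, fn, tn = 40, 5, 10, 45
    assert (tp + tn) / 100 == pytest.approx(0.85)


def test_kappa_extremes():
    assert kappa(50, 0, 0, 50) == pytest.approx(1.0)
    # constant-positive classifier on balanced data
    assert kappa(50, 50, 0, 0) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        kappa(100, 0, 0, 0)  # pe = 1


def test_auc_hand_computation():
    # concordant pairs 3/4
    assert auc([0.9, 0.8, 0.4, 0.3], [True, False, True, False]) == pytest.approx(0.75)
    assert auc([0.5, 0.5, 0.5, 0.5], [True, False, True, False]) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        auc([0.1, 0.2], [True, True])


def _brute_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def test_metric_oracles_on_random_instances():
    """kappa and auc agree with brute force (and sklearn) on 500 instances."""
    rng = np.random.default_rng(123)
    for _ in range(500):
        n = int(rng.integers(4, 30))
        labels = rng.random(n) < 0.5
        if labels.all() or not labels.any():
            continue
        scores = np.round(rng.random(n), 2)  # ties happen
        assert auc(scores, labels) == pytest.approx(_brute_auc(scores, labels), abs=1e-12)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        preds = scores >= 0.5
        tp, fp, fn, tn = confusion(labels, preds)
        if preds.all() or not preds.any():
            continue
        assert kappa(tp, fp, fn, tn) == pytest.approx(
            cohen_kappa_score(labels, preds), abs=1e-12
        )


def _table(features, labels, events=None, coords=None):
    df = pd.DataFrame(features, columns=FEATURES8[: len(features[0])])
    for f in FEATURES8[len(features[0]) :]:
        df[f] = 0.0
    df["label"] = labels
    df["event_id"] = events if events is not None else ["."] * len(df)
    n = len(df)
    df["chrom_l"] = coords[0] if coords else ["chr1"] * n
    df["pos_l"] = coords[1] if coords else list(range(n))
    df["strand_l"] = "+"
    df["chrom_r"] = "chr2"
    df["pos_r"] = coords[2] if coords else list(range(n))
    df["strand_r"] = "+"
    return df


def test_dedup_collapses_within_event_only():
    df = _table(
        [[1.0], [1.0], [1.0]],
        [True, True, True],
        events=["E1", "E1", "E2"],
        coords=(["chr1"] * 3, [5, 5, 5], [9, 9, 9]),
    )
    out = deduplicate(df)
    assert len(out) == 2  # E1 duplicates collapse, E2 kept
    assert set(out["event_id"]) == {"E1", "E2"}


def test_dedup_false_rows_key_on_junction_and_features():
    df = _table(
        [[1.0], [1.0], [1.0]],
        [False, False, False],
        coords=(["chr1"] * 3, [5, 5, 80], [9, 9, 9]),
    )
    out = deduplicate(df)
    assert len(out) == 2


def test_dedup_empty_table():
    df = _table([[1.0]], [True], events=["E"]).iloc[:0]
    assert len(deduplicate(df)) == 0


def _labelled_tables(n_tables, n_rows, seed=0, sep=2.0):
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_tables):
        y = rng.random(n_rows) < 0.25
        X = rng.normal(0, 1, size=(n_rows, 3)) + sep * y[:, None]
        df = pd.DataFrame(X, columns=["score_is_duplicate", "coefficient_variation",
                                      "score_break_length"])
        df["label"] = y
        df["event_id"] = "."
        tables.append(df)
    return tables


def test_five_genomes_give_fifteen_performance_points():
    runs = make_runs(_labelled_tables(5, 60), n_repeats=3, base_seed=1)
    assert len(runs) == 15
    assert [spec.run_id for spec, _, _ in runs] == [
        f"r{i}" for i in range(1, 6) for _ in range(3)
    ]
    # run rX pools genomes 1..X
    sizes = {spec.run_id: len(tr) + len(te) for spec, tr, te in runs}
    assert sizes["r5"] == 5 * 60


def test_splits_are_deterministic_and_two_thirds():
    t = _labelled_tables(1, 90)
    a = make_runs(t, n_repeats=2, base_seed=7)
    b = make_runs(t, n_repeats=2, base_seed=7)
    for (sa, tra, tea), (sb, trb, teb) in zip(a, b):
        assert sa == sb
        pd.testing.assert_frame_equal(tra, trb)
        assert len(tra) == 60 and len(tea) == 30


def test_single_genome_gives_three_datasets():
    assert len(make_runs(_labelled_tables(1, 40), n_repeats=3)) == 3


@pytest.mark.parametrize("method", METHODS)
def test_separable_data_scores_perfectly(method):
    table = _labelled_tables(1, 120, seed=3, sep=8.0)[0]
    feats = ["score_is_duplicate", "coefficient_variation", "score_break_length"]
    model = train_model(table, method, feats, folds=3, seed=0)
    res = evaluate(model, table)
    assert res["AUC"] == pytest.approx(1.0)
    assert res["ACC"] == pytest.approx(1.0)
    assert res["Kappa"] == pytest.approx(1.0)


def test_permuted_labels_give_chance_auc():
    rng = np.random.default_rng(5)
    table = _labelled_tables(1, 2000, seed=4, sep=0.0)[0]  # labels independent of X
    feats = ["score_is_duplicate", "coefficient_variation", "score_break_length"]
    model = train_model(table, "knn", feats, folds=5, seed=0)
    test = _labelled_tables(1, 2000, seed=6, sep=0.0)[0]
    res = evaluate(model, test)
    assert abs(res["AUC"] - 0.5) < 0.05


def test_tuning_is_deterministic_given_seed():
    table = _labelled_tables(1, 150, seed=8, sep=1.0)[0]
    feats = ["score_is_duplicate", "coefficient_variation", "score_break_length"]
    p1 = train_model(table, "gbm", feats, folds=5, seed=3).best_params
    p2 = train_model(table, "gbm", feats, folds=5, seed=3).best_params
    assert p1 == p2


def test_degenerate_feature_dropped_with_warning():
    table = _labelled_tables(1, 80, seed=9, sep=3.0)[0]
    table["score_is_duplicate"] = 1.0
    feats = ["score_is_duplicate", "coefficient_variation", "score_break_length"]
    with pytest.warns(UserWarning, match="zero variance"):
        model = train_model(table, "rf", feats, folds=5, seed=0)
    assert model.features == ["coefficient_variation", "score_break_length"]


def test_single_class_training_rejected():
    table = _labelled_tables(1, 40, seed=1)[0]
    table["label"] = True
    with pytest.raises(ValueError, match="both classes"):
        train_model(table, "rf")


def test_protocol_reports_every_method_and_run():
    tables = _labelled_tables(2, 50, seed=2, sep=4.0)
    points = run_protocol(tables, methods=("knn", "svm_rbf"), n_repeats=2, folds=4, base_seed=0)
    assert len(points) == 2 * 2 * 2  # runs x repeats x methods
    agg = aggregate_metrics(points)
    assert set(agg["method"]) == {"knn", "svm_rbf"}
    assert {"AUC_mean", "AUC_std", "Kappa_mean"} <= set(agg.columns)


def test_feature_report_lists_each_feature_once():
    rng = np.random.default_rng(11)
    y = rng.random(200) < 0.5
    df = pd.DataFrame({f: rng.normal(size=200) for f in FEATURES8})
    df["score_has_repeat"] = 0.0  # constant -> no discriminative power
    df["score_is_duplicate"] = y.astype(float)  # label-equal
    df["label"] = y
    rep = feature_selection_report(df)
    assert sorted(rep["feature"]) == sorted(FEATURES8)
    row = rep.set_index("feature")
    assert row.loc["score_has_repeat", "zero_variance"]
    assert row.loc["score_has_repeat", "univariate_auc"] == pytest.approx(0.5)
    assert row.loc["score_is_duplicate", "univariate_auc"] == pytest.approx(1.0)
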