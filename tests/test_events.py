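"""Event pipeline: score filter, aggregation, Gingeras classes,
annotation-based reclassification, features and the threshold sweep."""

import numpy as np
import pandas as pd
import pytest

from chimerabench.events import (
    MAX_DISTANCE,
    GeneLocator,
    aggregate_events,
    annotate_and_reclassify,
    build_event_table,
    classify_gingeras,
    event_features,
    label_events,
    score_filter,
    threshold_sweep,
    train_event_classifier,
)
from chimerabench.mutate import FusionTruth
from chimerabench.reference import GeneModel


def _cands(rows):
    base = {
        "read_id": [f"r{i}" for i in range(len(rows))],
        "chrom_l": [], "pos_l": [], "strand_l": [],
        "chrom_r": [], "pos_r": [], "strand_r": [],
        "score": [], "label": [], "class_hint": [], "event_id": [],
        "break_support": [],
    }
    for r in rows:
        base["chrom_l"].append(r[0]); base["pos_l"].append(r[1]); base["strand_l"].append(r[2])
        base["chrom_r"].append(r[3]); base["pos_r"].append(r[4]); base["strand_r"].append(r[5])
        base["score"].append(r[6] if len(r) > 6 else 1.0)
        base["label"].append(r[7] if len(r) > 7 else False)
        base["class_hint"].append(1)
        base["event_id"].append(".")
        base["break_support"].append(r[8] if len(r) > 8 else [3, 3, 3])
    return pd.DataFrame(base)


def test_score_filter_bounds_and_monotonicity():
    df = _cands([("chr1", 10, "+", "chr2", 20, "+", s) for s in (0.1, 0.75, 0.95, 1.0)])
    assert len(score_filter(df, 0.0)) == 4
    assert set(score_filter(df, 1.0)["score"]) == {1.0}
    k07 = set(score_filter(df, 0.7)["read_id"])
    k09 = set(score_filter(df, 0.9)["read_id"])
    assert k09 <= k07
    with pytest.raises(ValueError):
        score_filter(df, 1.5)


def test_identical_junctions_aggregate_to_one_event():
    df = _cands([("chr1", 100, "+", "chr2", 500, "+")] * 5)
    ev = aggregate_events(df)
    assert len(ev) == 1
    assert ev.iloc[0]["junction_support"] == 5


def test_distant_junctions_stay_separate():
    df = _cands([("chr1", 100, "+", "chr2", 500, "+"),
                 ("chr1", 1100, "+", "chr2", 500, "+")])
    assert len(aggregate_events(df, cluster_tolerance=5)) == 2


def test_single_linkage_chains_within_tolerance():
    # coordinates 0, 3, 6 with tolerance 3 chain into one event
    df = _cands([("chr1", 0, "+", "chr2", 500, "+"),
                 ("chr1", 3, "+", "chr2", 500, "+"),
                 ("chr1", 6, "+", "chr2", 500, "+")])
    ev = aggregate_events(df, cluster_tolerance=3)
    assert len(ev) == 1
    assert ev.iloc[0]["posA"] == 3  # per-side median


def test_mate_swapped_sides_cluster_together():
    df = _cands([("chr1", 100, "+", "chr2", 500, "+"),
                 ("chr2", 500, "+", "chr1", 100, "+")])
    assert len(aggregate_events(df)) == 1


def test_support_conservation_on_random_candidates():
    rng = np.random.default_rng(0)
    rows = [("chr1", int(rng.integers(0, 5000)), "+",
             "chr2", int(rng.integers(0, 5000)), "+") for _ in range(200)]
    ev = aggregate_events(_cands(rows))
    assert ev["junction_support"].sum() == 200


def test_gingeras_classes():
    assert classify_gingeras("chr1", "+", "chr2", "+") == 1
    assert classify_gingeras("chr1", "+", "chr1", "-") == 3
    assert classify_gingeras("chr1", "+", "chr1", "+") == 2  # order/distance discordance


GENES = [
    GeneModel("G1", "chr1", "+", ((100, 200), (300, 400))),
    GeneModel("G2", "chr1", "+", ((1000, 1200),)),
    GeneModel("PG1", "chr2", "+", ((50, 250),), "pseudogene", parent_id="G1"),
]


def _event(chromA, posA, chromB, posB):
    return {"chromA": chromA, "posA": posA, "strandA": "+",
            "chromB": chromB, "posB": posB, "strandB": "+",
            "junction_support": 3, "break_support": [2, 2, 2]}


def test_reclassification_rules():
    loc = GeneLocator(GENES)
    assert annotate_and_reclassify(_event("chr1", 150, "chr1", 350), loc)[0] == "splicing"
    assert annotate_and_reclassify(_event("chr1", 150, "chr2", 100), loc)[0] == "artefact"
    assert annotate_and_reclassify(_event("chr1", 150, "chr1", 1100), loc)[0] == "chimera"
    status, flag = annotate_and_reclassify(_event("chr1", 150, "chr1", 5000), loc)
    assert status == "chimera" and flag == "intergenic"


def test_event_feature_values():
    feats = event_features(_event("chr1", 1000, "chr2", 500))
    assert feats["fusion_distance"] == MAX_DISTANCE
    feats = event_features(_event("chr1", 1000, "chr1", 51000))
    assert feats["fusion_distance"] == 50000
    assert feats["coefficient_variation"] == 0.0  # constant pooled support
    assert feats["junction_support"] == 3.0


def _fusion(chrom5="chr1", bp5=151, chrom3="chr1", bp3=1100):
    return FusionTruth(
        event_id="T1a", gene5="G1", gene5_exons=(0, 1), gene3="G2", gene3_exons=(0, 1),
        chrom5=chrom5, breakpoint5=bp5, chrom3=chrom3, breakpoint3=bp3,
        reciprocal_id="T1b",
    )


def test_event_labelling_within_tolerance():
    ev = pd.DataFrame([_event("chr1", 150, "chr1", 1100)])
    assert label_events(ev, [_fusion()], tolerance=5).tolist() == [True]
    assert label_events(ev, [_fusion(bp3=1200)], tolerance=5).tolist() == [False]


def test_build_event_table_filters_artefacts_and_splicing():
    df = _cands([
        ("chr1", 150, "+", "chr1", 1100, "+", 0.99, True),   # true chimera
        ("chr1", 150, "+", "chr2", 100, "+", 0.99, False),   # touches pseudogene
        ("chr1", 150, "+", "chr1", 350, "+", 0.99, False),   # same gene
        ("chr1", 150, "+", "chr1", 1100, "+", 0.2, True),    # filtered by score
    ])
    ev = build_event_table(df, GENES, [_fusion()], threshold=0.7)
    assert len(ev) == 1
    assert ev.iloc[0]["label"]
    assert ev.iloc[0]["junction_support"] == 1
    full = build_event_table(df, GENES, [_fusion()], threshold=0.7, keep_all_statuses=True)
    assert sorted(full["annotation_status"]) == ["artefact", "chimera", "splicing"]


def test_sweep_perfect_detector_has_zero_fdr():
    df = _cands([("chr1", 150, "+", "chr1", 1100, "+", 1.0, True)] * 4)
    sweep = threshold_sweep(df, GENES, [_fusion()], thresholds=(0.0, 0.7))
    read_rows = sweep[sweep["level"] == "read"]
    assert (read_rows["FDR"] == 0.0).all()
    assert (read_rows["PPR"] == 1.0).all()


def test_sweep_read_counts_monotone_in_threshold():
    rng = np.random.default_rng(3)
    rows = [("chr1", int(rng.integers(0, 3000)), "+", "chr2", 500, "+",
             float(rng.random()), bool(rng.random() < 0.3)) for _ in range(100)]
    sweep = threshold_sweep(_cands(rows), GENES, [_fusion()],
                            thresholds=(0.0, 0.5, 0.9))
    reads = sweep[sweep["level"] == "read"].sort_values("threshold")
    kept = (reads["TP"] + reads["FP"]).tolist()
    assert kept == sorted(kept, reverse=True)
    assert (reads["TP"].diff().dropna() <= 0).all()


def _event_tables(n_tables, n_rows, seed=0, sep=6.0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_tables):
        y = rng.random(n_rows) < 0.3
        df = pd.DataFrame({
            "coefficient_variation": rng.normal(0, 1, n_rows) - sep * y,
            "fusion_distance": rng.normal(10, 1, n_rows) + sep * y,
            "junction_support": rng.normal(5, 1, n_rows) + sep * y,
            "label": y,
            "event_id": ".",
        })
        out.append(df)
    return out


def test_event_classifier_protocol_shape_and_separability():
    tables = _event_tables(2, 80, seed=1)
    points = train_event_classifier(tables, methods=("knn", "gbm"), n_repeats=3, folds=4)
    # final-run protocol: 3 repeats x 2 methods, with mean/sd aggregation
    assert len(points) == 6
    assert set(points["method"]) == {"knn", "gbm"}
    assert points["ACC"].mean() > 0.95
    from chimerabench.classify import aggregate_metrics

    agg = aggregate_metrics(points)
    assert {"ACC_mean", "ACC_std", "Kappa_mean", "Kappa_std"} <= set(agg.columns)
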