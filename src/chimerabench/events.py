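"""From candidate reads to chimeric events.

Candidates that pass the chimera-score filter (default 0.7) are aggregated:
junction side-pairs within a few bases of each other (single linkage, both
sides, same chromosome/strand pair) form one event whose coordinates are the
per-side medians. Events are classified on the Gingeras taxonomy — class 1
inter-chromosomal, class 3 same chromosome opposite strands, class 2 same
chromosome/strand with discordant order or excessive distance; class 4
(different alleles) is never emitted because the simulation is haploid —
then reclassified against the annotation: events inside a single gene are
splicing, events touching a pseudogene are artefacts, the rest remain
chimeras. Three event features feed the event-level classifier:
coefficient_variation of the pooled break support, fusion_distance and
junction_support.
"""

from __future__ import annotations

from bisect import bisect_right


import numpy as np
import pandas as pd

from .classify import run_protocol
from .mutate import FusionTruth
from .reference import GeneModel

MAX_DISTANCE = 2**31 - 1  # sentinel for inter-chromosomal fusion distance
EVENT_FEATURES = ["coefficient_variation", "fusion_distance", "junction_support"]
DEFAULT_THRESHOLDS = (0.0, 0.7, 0.9, 0.95, 0.99)


def score_filter(candidates: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Keep candidates whose chimera score reaches the threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if "score" not in candidates.columns:
        raise ValueError("candidates must carry a read-level model 'score' column")
    return candidates[candidates["score"] >= threshold].reset_index(drop=True)


def _canonical_sides(row) -> tuple:
    a = (row.chrom_l, int(row.pos_l), row.strand_l)
    b = (row.chrom_r, int(row.pos_r), row.strand_r)
    return (a, b, False) if a <= b else (b, a, True)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def aggregate_events(candidates: pd.DataFrame, cluster_tolerance: int = 5) -> pd.DataFrame:
    """Single-linkage clustering of junction side-pairs into events.

    Candidates cluster when both sides lie within ``cluster_tolerance``
    bases (same chromosome/strand pair; sides are compared unordered, so a
    mate seeing the junction from the other direction still joins). The sum
    of ``junction_support`` over events equals the number of candidates.
    """
    if candidates.empty:
        return pd.DataFrame(
            columns=["chromA", "posA", "strandA", "chromB", "posB", "strandB",
                     "junction_support", "read_ids", "break_support", "truth_events",
                     "class_hint"]
        )
    sides = candidates.apply(_canonical_sides, axis=1)
    keys = [(a[0], a[2], b[0], b[2]) for a, b, _ in sides]
    posA = np.array([a[1] for a, _, _ in sides])
    posB = np.array([b[1] for _, b, _ in sides])

    events = []
    frame = candidates.reset_index(drop=True)
    group_of = pd.Series(keys)
    for key in sorted(set(keys)):
        idx = np.nonzero((group_of == key).to_numpy())[0]
        pa, pb = posA[idx], posB[idx]
        order = np.argsort(pa, kind="stable")
        uf = _UnionFind(len(idx))
        for oi in range(len(order)):
            i = order[oi]
            for oj in range(oi - 1, -1, -1):
                j = order[oj]
                if pa[i] - pa[j] > cluster_tolerance:
                    break
                if abs(int(pb[i]) - int(pb[j])) <= cluster_tolerance:
                    uf.union(i, j)
        clusters: dict[int, list[int]] = {}
        for i in range(len(idx)):
            clusters.setdefault(uf.find(i), []).append(i)
        chromA, strandA, chromB, strandB = key[0], key[1], key[2], key[3]
        for members in clusters.values():
            rows = frame.iloc[idx[members]]
            pooled = [v for bs in rows["break_support"] for v in bs] \
                if "break_support" in rows.columns else []
            truth_events = sorted(set(e for e in rows.get("event_id", pd.Series([])) if e != "."))
            hints = rows["class_hint"].tolist() if "class_hint" in rows.columns else []
            events.append(
                {
                    "chromA": chromA,
                    "posA": int(np.median(pa[members])),
                    "strandA": strandA,
                    "chromB": chromB,
                    "posB": int(np.median(pb[members])),
                    "strandB": strandB,
                    "junction_support": len(members),
                    "read_ids": rows["read_id"].tolist(),
                    "break_support": pooled,
                    "truth_events": truth_events,
                    "class_hint": int(pd.Series(hints).mode().iloc[0]) if hints else 0,
                }
            )
    return pd.DataFrame(events)


def classify_gingeras(chromA: str, strandA: str, chromB: str, strandB: str) -> int:
    """Gingeras event class: 1 inter-chromosomal, 3 same chromosome opposite
    strands, 2 same chromosome/strand (discordant order or distance). Class 4
    (different alleles) is never produced by a haploid simulation."""
    if chromA != chromB:
        return 1
    if strandA != strandB:
        return 3
    return 2


class GeneLocator:
    """Point-in-gene queries over a non-overlapping gene annotation."""

    def __init__(self, genes: list[GeneModel]):
        self._by_chrom: dict[str, tuple[list[int], list[int], list[GeneModel]]] = {}
        for chrom in {g.chrom for g in genes}:
            sub = sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.start)
            self._by_chrom[chrom] = ([g.start for g in sub], [g.end for g in sub], sub)

    def gene_at(self, chrom: str, pos: int) -> GeneModel | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, sub = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos < ends[i]:
            return sub[i]
        return None


def annotate_and_reclassify(event_row, locator: GeneLocator) -> tuple[str, str]:
    """(annotation_status, flag) for one event.

    A side touching a pseudogene makes the event an artefact; both sides in
    the same gene make it (alternative) splicing; anything else remains a
    chimera, flagged 'intergenic' when a side falls outside the annotation.
    """
    ga = locator.gene_at(event_row["chromA"], int(event_row["posA"]))
    gb = locator.gene_at(event_row["chromB"], int(event_row["posB"]))
    for g in (ga, gb):
        if g is not None and g.biotype == "pseudogene":
            return "artefact", ""
    if ga is not None and gb is not None and ga.gene_id == gb.gene_id:
        return "splicing", ""
    flag = "intergenic" if (ga is None or gb is None) else ""
    return "chimera", flag


def event_features(event_row) -> dict[str, float]:
    """coefficient_variation of the pooled break support, fusion_distance
    (sentinel for inter-chromosomal events) and junction_support."""
    pooled = np.asarray(event_row["break_support"], dtype=float)
    cv = float(pooled.std() / pooled.mean()) if pooled.size and pooled.mean() > 0 else 0.0
    if event_row["chromA"] == event_row["chromB"]:
        dist = abs(int(event_row["posA"]) - int(event_row["posB"]))
    else:
        dist = MAX_DISTANCE
    return {
        "coefficient_variation": cv,
        "fusion_distance": float(dist),
        "junction_support": float(event_row["junction_support"]),
    }


def label_events(events: pd.DataFrame, fusions: list[FusionTruth], tolerance: int = 5) -> pd.Series:
    """TRUE iff the event matches a truth fusion junction within tolerance."""
    truth = [((f.chrom5, f.breakpoint5 - 1), (f.chrom3, f.breakpoint3)) for f in fusions]

    def close(side, t):
        return side[0] == t[0] and abs(side[1] - t[1]) <= tolerance

    labels = []
    for _, e in events.iterrows():
        a = (e["chromA"], int(e["posA"]))
        b = (e["chromB"], int(e["posB"]))
        ok = any(
            (close(a, t5) and close(b, t3)) or (close(b, t5) and close(a, t3))
            for t5, t3 in truth
        )
        labels.append(ok)
    return pd.Series(labels, index=events.index)


def build_event_table(
    scored_candidates: pd.DataFrame,
    genes: list[GeneModel],
    fusions: list[FusionTruth],
    threshold: float = 0.7,
    cluster_tolerance: int = 5,
    tolerance: int = 5,
    keep_all_statuses: bool = False,
) -> pd.DataFrame:
    """Filter by chimera score, aggregate, classify, annotate and label.

    By default only events whose annotation status remains 'chimera' are
    returned (splicing and artefact events are filtered out, as in the
    'filtered aggregation' protocol)."""
    kept = score_filter(scored_candidates, threshold)
    events = aggregate_events(kept, cluster_tolerance)
    if events.empty:
        return events
    locator = GeneLocator(genes)
    status, flags, classes, feats = [], [], [], []
    for _, e in events.iterrows():
        st, fl = annotate_and_reclassify(e, locator)
        status.append(st)
        flags.append(fl)
        classes.append(classify_gingeras(e["chromA"], e["strandA"], e["chromB"], e["strandB"]))
        feats.append(event_features(e))
    events = events.assign(
        annotation_status=status,
        flag=flags,
        gingeras_class=classes,
        **{k: [f[k] for f in feats] for k in EVENT_FEATURES},
    )
    events["label"] = label_events(events, fusions, tolerance)
    if not keep_all_statuses:
        events = events[events["annotation_status"] == "chimera"].reset_index(drop=True)
    return events


def train_event_classifier(
    event_tables: list[pd.DataFrame],
    methods=("knn", "svm_rbf", "rf", "gbm"),
    n_repeats: int = 3,
    folds: int = 10,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Event-level protocol: same repeated-split, 10-fold CV recipe as the
    read level, on the three event features."""
    if len(event_tables) < 1:
        raise ValueError("need at least one labelled event table")
    final = [f"r{len(event_tables)}"]
    return run_protocol(
        event_tables,
        methods=methods,
        features=EVENT_FEATURES,
        n_repeats=n_repeats,
        folds=folds,
        base_seed=base_seed,
        runs=final,
    )


def threshold_sweep(
    scored_candidates: pd.DataFrame,
    genes: list[GeneModel],
    fusions: list[FusionTruth],
    thresholds=DEFAULT_THRESHOLDS,
    cluster_tolerance: int = 5,
    tolerance: int = 5,
) -> pd.DataFrame:
    """Precision (PPR) and FDR at read and event level per score threshold.

    Sensitivity is measured against the TRUE candidates present at
    threshold 0 (read level) and the truth fusion set (event level).
    """
    total_true_reads = int(scored_candidates["label"].sum())
    rows = []
    for t in thresholds:
        kept = score_filter(scored_candidates, t)
        tp_r = int(kept["label"].sum())
        fp_r = len(kept) - tp_r
        rows.append(_sweep_row(t, "read", tp_r, fp_r, tp_r / total_true_reads if total_true_reads else np.nan))
        events = build_event_table(
            kept.assign(score=1.0), genes, fusions, threshold=0.0,
            cluster_tolerance=cluster_tolerance, tolerance=tolerance,
        )
        tp_e = int(events["label"].sum()) if len(events) else 0
        fp_e = len(events) - tp_e
        n_truth = len({f.event_id for f in fusions})
        rows.append(_sweep_row(t, "event", tp_e, fp_e, tp_e / n_truth if n_truth else np.nan))
    return pd.DataFrame(rows)


def _sweep_row(threshold: float, level: str, tp: int, fp: int, sens: float) -> dict:
    total = tp + fp
    return {
        "threshold": threshold,
        "level": level,
        "TP": tp,
        "FP": fp,
        "PPR": tp / total if total else np.nan,
        "FDR": fp / total if total else np.nan,
        "sensitivity": sens,
    }
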