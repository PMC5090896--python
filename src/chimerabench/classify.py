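"""Read-level classification protocol.

Reproduces the benchmark's modelling recipe: duplicate candidate rows are
collapsed (unique reads per chimera), genomes are pooled progressively
(run r1 uses one genome, r5 all five), each run is split 2/3 train / 1/3
test three times, and each of four classifiers (KNN, RBF-SVM, random
forest, gradient boosting) is tuned by 10-fold cross-validated AUC over a
small grid and refit. Performance is reported as accuracy, sensitivity,
specificity, Cohen's kappa and AUC, aggregated as mean +/- sd over the
repeats.

``kappa`` and ``auc`` are implemented directly from their definitions
(chance-corrected agreement; Mann-Whitney rank statistic with ties at 0.5)
so they can be checked against independent oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .profiler import FEATURES8, TOP3

METHODS = ("knn", "svm_rbf", "rf", "gbm")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def kappa(tp: int, fp: int, fn: int, tn: int) -> float:
    """Cohen's kappa from confusion counts: (po - pe) / (1 - pe)."""
    n = tp + fp + fn + tn
    if n == 0 or min(tp + fn, fp + tn) < 0:
        raise ValueError("invalid confusion counts")
    po = (tp + tn) / n
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    if pe == 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic (ties 0.5)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    npos = int(labels.sum())
    nneg = labels.size - npos
    if npos == 0 or nneg == 0:
        raise ValueError("auc needs at least one observation of each class")
    ranks = rankdata(scores)
    return (ranks[labels].sum() - npos * (npos + 1) / 2) / (npos * nneg)


def confusion(labels, predictions) -> tuple[int, int, int, int]:
    labels = np.asarray(labels, dtype=bool)
    predictions = np.asarray(predictions, dtype=bool)
    tp = int((labels & predictions).sum())
    fp = int((~labels & predictions).sum())
    fn = int((labels & ~predictions).sum())
    tn = int((~labels & ~predictions).sum())
    return tp, fp, fn, tn


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


def deduplicate(table: pd.DataFrame, features: list[str] = FEATURES8) -> pd.DataFrame:
    """Collapse duplicate candidate rows.

    TRUE rows are unique per (event, feature vector): many reads covering
    the same junction share identical break k-mers and hence identical
    features. FALSE rows are unique per (junction coordinates, feature
    vector). Identical vectors from *different* events are kept.
    """
    if table.empty:
        return table.copy()
    true_rows = table[table["label"]]
    false_rows = table[~table["label"]]
    true_keys = ["event_id"] + features
    true_dedup = true_rows.drop_duplicates(subset=true_keys)
    junction_cols = [c for c in ("chrom_l", "pos_l", "strand_l", "chrom_r", "pos_r", "strand_r")
                     if c in table.columns]
    false_dedup = false_rows.drop_duplicates(subset=junction_cols + features)
    return pd.concat([true_dedup, false_dedup]).sort_index().reset_index(drop=True)


@dataclass(frozen=True)
class RunSpec:
    run_id: str  # r1 ... rN
    n_genomes: int
    repeat_index: int  # 1-based
    split_seed: int
    train_fraction: float = 2 / 3


def make_runs(
    tables: list[pd.DataFrame],
    n_repeats: int = 3,
    base_seed: int = 0,
) -> list[tuple[RunSpec, pd.DataFrame, pd.DataFrame]]:
    """Progressive sampling: run rX pools genomes 1..X; each run is split
    into 2/3 train and 1/3 test with a fresh random (non-stratified) split
    per repeat. Single-class training splits are re-drawn with a warning."""
    out = []
    for run_idx in range(1, len(tables) + 1):
        pooled = pd.concat(tables[:run_idx], ignore_index=True)
        for rep in range(1, n_repeats + 1):
            seed = base_seed + 1000 * run_idx + rep
            rng = np.random.default_rng(seed)
            for _attempt in range(20):
                perm = rng.permutation(len(pooled))
                n_train = int(round(len(pooled) * 2 / 3))
                train = pooled.iloc[perm[:n_train]].reset_index(drop=True)
                test = pooled.iloc[perm[n_train:]].reset_index(drop=True)
                if train["label"].nunique() == 2:
                    break
                warnings.warn(f"single-class training split for r{run_idx} repeat {rep}; re-drawn")
            out.append((RunSpec(f"r{run_idx}", run_idx, rep, seed), train, test))
    return out


# ---------------------------------------------------------------------------
# Model training
# ---------------------------------------------------------------------------


def _median_heuristic_gammas(X: np.ndarray, rng: np.random.Generator) -> list[float]:
    """RBF widths around the median pairwise distance of (scaled) inputs."""
    sub = X if len(X) <= 500 else X[rng.choice(len(X), 500, replace=False)]
    d = pairwise_distances(StandardScaler().fit_transform(sub))
    sigma = float(np.median(d[np.triu_indices_from(d, k=1)]))
    sigma = max(sigma, 1e-6)
    return [1.0 / (2.0 * (f * sigma) ** 2) for f in (0.5, 1.0, 2.0)]


def _grid(method: str, X: np.ndarray, seed: int) -> tuple[object, list[dict]]:
    """Estimator plus tuning grid, ordered simplest model first so that
    cross-validation ties resolve toward the simpler hyper-parameters."""
    rng = np.random.default_rng(seed)
    if method == "knn":
        est = Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier())])
        grid = [{"clf__n_neighbors": [k]} for k in (11, 9, 7, 5)]
    elif method == "svm_rbf":
        est = Pipeline(
            [("scale", StandardScaler()),
             ("clf", SVC(kernel="rbf", probability=True, random_state=seed))]
        )
        gammas = _median_heuristic_gammas(X, rng)
        grid = [{"clf__C": [c], "clf__gamma": [g]} for c in (0.25, 1.0, 4.0) for g in gammas]
    elif method == "rf":
        est = RandomForestClassifier(n_estimators=500, random_state=seed)
        mmax = X.shape[1]
        grid = [{"max_features": [m]} for m in (1, 2, 3) if m <= mmax]
    elif method == "gbm":
        est = GradientBoostingClassifier(learning_rate=0.1, random_state=seed)
        grid = [
            {"max_depth": [d], "n_estimators": [n]}
            for d in (1, 2, 3)
            for n in (50, 100, 150)
        ]
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return est, grid


@dataclass
class FittedModel:
    method: str
    features: list[str]
    search: GridSearchCV

    @property
    def best_params(self) -> dict:
        return self.search.best_params_

    def predict_scores(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.features].to_numpy(dtype=float)
        proba = self.search.predict_proba(X)
        pos = list(self.search.classes_).index(True)
        return proba[:, pos]


def train_model(
    train: pd.DataFrame,
    method: str,
    features: list[str] = TOP3,
    folds: int = 10,
    seed: int = 0,
) -> FittedModel:
    """Tune by 10-fold cross-validated AUC over the method's grid and refit.

    Zero-variance features in the training data are dropped with a warning;
    grid ties resolve to the simplest model (grid order).
    """
    if train["label"].nunique() < 2:
        raise ValueError("training data must contain both classes")
    kept = []
    for f in features:
        if train[f].nunique() > 1:
            kept.append(f)
        else:
            warnings.warn(f"feature {f} has zero variance in training data; dropped")
    if not kept:
        raise ValueError("all features are degenerate")
    X = train[kept].to_numpy(dtype=float)
    y = train["label"].to_numpy(dtype=bool)
    est, grid = _grid(method, X, seed)
    n_splits = min(folds, int(min(y.sum(), (~y).sum())))
    cv = StratifiedKFold(n_splits=max(2, n_splits), shuffle=True, random_state=seed)
    search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, refit=True, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(X, y)
    return FittedModel(method=method, features=kept, search=search)


def evaluate(model: FittedModel, test: pd.DataFrame, threshold: float = 0.5) -> dict:
    """Confusion at the 0.5 threshold plus threshold-free AUC on held-out data."""
    y = test["label"].to_numpy(dtype=bool)
    scores = model.predict_scores(test)
    preds = scores >= threshold
    tp, fp, fn, tn = confusion(y, preds)
    n = len(y)
    out = {
        "method": model.method,
        "ACC": (tp + tn) / n,
        "Sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "Specificity": tn / (tn + fp) if tn + fp else np.nan,
        "Kappa": kappa(tp, fp, fn, tn) if 0 < y.sum() < n else np.nan,
        "AUC": auc(scores, y) if 0 < y.sum() < n else np.nan,
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
    }
    return out


METRIC_COLS = ["ACC", "Sensitivity", "Specificity", "Kappa", "AUC"]


def run_protocol(
    tables: list[pd.DataFrame],
    methods: tuple[str, ...] = METHODS,
    features: list[str] = TOP3,
    n_repeats: int = 3,
    folds: int = 10,
    base_seed: int = 0,
    runs: list[str] | None = None,
) -> pd.DataFrame:
    """Full progressive-sampling benchmark: one row per (method, run, repeat).

    ``runs`` restricts which progressive runs are trained (e.g. ["r1", "r5"]).
    """
    rows = []
    for spec, train, test in make_runs(tables, n_repeats=n_repeats, base_seed=base_seed):
        if runs is not None and spec.run_id not in runs:
            continue
        for method in methods:
            model = train_model(train, method, features, folds=folds, seed=spec.split_seed)
            res = evaluate(model, test)
            res.update({"run_id": spec.run_id, "repeat": spec.repeat_index,
                        "n_train": len(train), "n_test": len(test)})
            rows.append(res)
    return pd.DataFrame(rows)


def aggregate_metrics(points: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd of each metric over repeats, per (method, run)."""
    agg = points.groupby(["method", "run_id"])[METRIC_COLS].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg.reset_index()


def feature_selection_report(
    table: pd.DataFrame, features: list[str] = FEATURES8, seed: int = 0
) -> pd.DataFrame:
    """Univariate AUC and random-forest importance per feature.

    Zero-variance features (notably score_has_repeat on clean synthetic
    genomes) are flagged as carrying no discriminative power.
    """
    y = table["label"].to_numpy(dtype=bool)
    X = table[features].to_numpy(dtype=float)
    rf = RandomForestClassifier(n_estimators=200, random_state=seed).fit(X, y)
    rows = []
    for i, f in enumerate(features):
        const = table[f].nunique() <= 1
        rows.append(
            {
                "feature": f,
                "univariate_auc": 0.5 if const else auc(table[f].to_numpy(float), y),
                "rf_importance": float(rf.feature_importances_[i]),
                "zero_variance": bool(const),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("rf_importance", ascending=False).reset_index(drop=True)
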