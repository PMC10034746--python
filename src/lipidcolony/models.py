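"""Multivariate models linking per-cell lipid profiles to differentiation
stage, phenotype, and lineage.

The suite covers: k-means fluorescence phenotype labeling, PLS regression of
differentiation day on lipid abundances, decision-tree staging with the
pluripotent/intermediate/differentiated class collapse and impurity-based
predictor importance, PLS discriminant analysis with VIP-based backward
variable trimming, a three-population PLS-DA projection space whose first
latent axis tracks time and second tracks lineage, per-day trajectory
summaries, and the two-group lineage comparison test.

Validation is always against an independent replicate (a second realization
of the experiment), never a random within-sample split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr, ttest_ind
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import accuracy_score, r2_score
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

STAGE_CLASSES = {  # fixed day partition of the 8-day protocol
    "pluripotent": (0, 1, 2),
    "intermediate": (3, 4, 5),
    "differentiated": (6, 7),
}
_DAY_TO_STAGE = {d: name for name, days in STAGE_CLASSES.items() for d in days}


def stage_of_day(day: int) -> str:
    if day not in _DAY_TO_STAGE:
        raise ValueError(f"day {day} outside the 0-7 protocol")
    return _DAY_TO_STAGE[day]


@dataclass
class LatentModel:
    """A fitted model plus the artifacts needed for biplots and reports."""

    kind: str                                   # PLSR | PLSDA | TREE | PROJECTION
    estimator: object
    feature_names: list[str]
    scores: np.ndarray | None = None            # per-training-cell latent coords
    loadings: np.ndarray | None = None          # per-feature weights
    trimmed_features: list[str] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    scaler: StandardScaler | None = None
    extra: dict = field(default_factory=dict)

    def card(self) -> dict:
        """JSON-serializable model card (hyperparameters, metrics, features)."""
        return {
            "kind": self.kind,
            "n_features": len(self.feature_names),
            "features": self.feature_names,
            "trimmed_features": self.trimmed_features,
            "metrics": {k: (v if not isinstance(v, np.generic) else v.item())
                        for k, v in self.metrics.items()},
        }

    def save_card(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.card(), indent=2, default=str))


# ---------------------------------------------------------------------------
# fluorescence phenotype labeling
# ---------------------------------------------------------------------------


def label_by_kmeans(fluor: np.ndarray, channel_names: tuple[str, str],
                    seed: int = 0) -> np.ndarray:
    """Label each cell as positive for one of two competing marker channels
    by 2-means clustering of the standardized intensities.

    The cluster whose standardized mean is higher in channel B than channel A
    is labeled ``channel_names[1]``-positive, and vice versa; invariant under
    swapping the channel order.  Constant intensities in both channels yield
    unlabeled cells with a warning.
    """
    X = np.asarray(fluor, float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("fluor must be (n_cells, 2)")
    if len(X) < 2:
        raise ValueError("need at least 2 cells")
    stds = X.std(axis=0)
    stds = np.where(stds <= 1e-9 * (np.abs(X).mean(axis=0) + 1.0), 0.0, stds)
    if np.all(stds == 0):
        warnings.warn("both channels constant: cells left unlabeled")
        return np.array([None] * len(X), dtype=object)
    Z = (X - X.mean(axis=0)) / np.where(stds == 0, 1.0, stds)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z)
    labels = km.labels_
    out = np.empty(len(X), dtype=object)
    # cluster -> channel with the higher standardized mean
    diff = [Z[labels == c].mean(axis=0) for c in (0, 1)]
    # assign each cluster the channel in which it dominates; break symmetric
    # ties by channel order
    ch_for_cluster = {}
    if diff[0][0] - diff[0][1] >= diff[1][0] - diff[1][1]:
        ch_for_cluster[0], ch_for_cluster[1] = channel_names[0], channel_names[1]
    else:
        ch_for_cluster[0], ch_for_cluster[1] = channel_names[1], channel_names[0]
    for c in (0, 1):
        out[labels == c] = f"{ch_for_cluster[c]}+"
    return out


# ---------------------------------------------------------------------------
# PLS regression (staging)
# ---------------------------------------------------------------------------


def fit_plsr(X: np.ndarray, y: np.ndarray, X_val: np.ndarray, y_val: np.ndarray,
             feature_names: list[str], n_components: int = 5,
             log_transform: bool = True) -> LatentModel:
    """PLS regression of differentiation day on standardized (by default
    log-transformed) abundances, validated on an independent replicate
    (reports validation R^2)."""
    prep = log_abundance if log_transform else lambda A: np.asarray(A, float)
    X = prep(X)
    X_val = prep(X_val)
    y = np.asarray(y, float)
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds the rank of X")
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, y)
    pred = pls.predict(np.asarray(X_val, float)).ravel()
    r2 = r2_score(np.asarray(y_val, float), pred)
    return LatentModel(
        kind="PLSR", estimator=pls, feature_names=list(feature_names),
        scores=pls.x_scores_, loadings=pls.x_loadings_,
        metrics={"validation_r2": float(r2), "n_components": n_components},
    )


# ---------------------------------------------------------------------------
# decision-tree staging
# ---------------------------------------------------------------------------


def fit_stage_tree(X: np.ndarray, y_day: np.ndarray, X_val: np.ndarray,
                   y_day_val: np.ndarray, feature_names: list[str],
                   max_depth: int = 8, min_samples_leaf: int = 50,
                   seed: int = 0) -> LatentModel:
    """CART tree predicting the day (8 classes) from per-cell abundances;
    reports 8-class validation accuracy on the replicate."""
    y_day = np.asarray(y_day, int)
    if len(np.unique(y_day)) < 2:
        raise ValueError("training labels contain a single class")
    tree = DecisionTreeClassifier(
        criterion="gini", max_depth=max_depth,
        min_samples_leaf=min_samples_leaf, random_state=seed)
    tree.fit(np.asarray(X, float), y_day)
    pred = tree.predict(np.asarray(X_val, float))
    acc8 = accuracy_score(np.asarray(y_day_val, int), pred)
    return LatentModel(
        kind="TREE", estimator=tree, feature_names=list(feature_names),
        metrics={"validation_accuracy_8class": float(acc8),
                 "max_depth": max_depth, "min_samples_leaf": min_samples_leaf},
        extra={"y_val": np.asarray(y_day_val, int), "pred_val": pred},
    )


def collapse_stages(y_day_true: np.ndarray, y_day_pred: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Collapse day labels through the fixed pluripotent (0-2) /
    intermediate (3-5) / differentiated (6-7) partition and recompute
    accuracy at the 3-class level."""
    true3 = np.array([stage_of_day(int(d)) for d in y_day_true])
    pred3 = np.array([stage_of_day(int(d)) for d in y_day_pred])
    return true3, pred3, float(accuracy_score(true3, pred3))


def predictor_importance(model: LatentModel) -> dict[str, float]:
    """Impurity-decrease importance of each feature, normalized to sum 1."""
    if model.kind != "TREE":
        raise ValueError("predictor importance is defined for tree models")
    imp = model.estimator.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return dict(zip(model.feature_names, imp.tolist()))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


def _onehot(labels: np.ndarray, classes: list) -> np.ndarray:
    Y = np.zeros((len(labels), len(classes)))
    for j, c in enumerate(classes):
        Y[np.asarray(labels) == c, j] = 1.0
    return Y


LOG_EPS = 1e-9


def log_abundance(X: np.ndarray) -> np.ndarray:
    """log(X + eps): ion abundances carry multiplicative noise, so the
    latent-variable models operate in log space by default."""
    return np.log(np.asarray(X, float) + LOG_EPS)


def fit_plsda(X: np.ndarray, labels: np.ndarray,
              X_val: np.ndarray | None, labels_val: np.ndarray | None,
              feature_names: list[str], n_components: int = 2,
              class_weighted: bool = True,
              log_transform: bool = True) -> LatentModel:
    """PLS discriminant analysis on (log-transformed, standardized)
    abundances with a one-hot class response.

    With ``class_weighted`` the one-hot columns are scaled so each class
    contributes equally to the response covariance regardless of size; the
    class decision is by nearest training-class centroid in predicted-
    response space, which stays calibrated under that scaling.  Reports
    validation accuracy on the held-out replicate (None if no validation
    set)."""
    prep = log_abundance if log_transform else lambda A: np.asarray(A, float)
    X = prep(X)
    labels = np.asarray(labels)
    classes = sorted(map(str, np.unique(labels).tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes in training")
    Y = _onehot(labels.astype(str), classes)
    if class_weighted:
        Y = Y / Y.sum(axis=0, keepdims=True) * (len(labels) / len(classes))
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, Y)
    resp_tr = pls.predict(X)
    centroids = np.vstack([resp_tr[labels.astype(str) == c].mean(axis=0)
                           for c in classes])

    def predict(Xq: np.ndarray) -> np.ndarray:
        resp = pls.predict(prep(Xq))
        d = np.linalg.norm(resp[:, None, :] - centroids[None, :, :], axis=2)
        return np.array([classes[i] for i in np.argmin(d, axis=1)])

    metrics: dict = {"n_components": n_components, "classes": classes}
    if X_val is not None and labels_val is not None and len(X_val):
        val_labels = np.asarray(labels_val).astype(str)
        present = np.isin(val_labels, classes)
        if present.any():
            acc = accuracy_score(val_labels[present],
                                 predict(np.asarray(X_val)[present]))
            metrics["validation_accuracy"] = float(acc)
        else:
            metrics["validation_accuracy"] = None
    model = LatentModel(
        kind="PLSDA", estimator=pls, feature_names=list(feature_names),
        scores=pls.x_scores_, loadings=pls.x_loadings_, metrics=metrics,
    )
    model.extra["predict"] = predict
    return model


def vip_scores(model: LatentModel) -> np.ndarray:
    """Variable importance in projection for a fitted PLS model.

    VIP_j = sqrt( p * sum_a(SSY_a * (w_ja / ||w_a||)^2) / sum_a SSY_a )
    where SSY_a is the response variance explained by component a.  Features
    with VIP < 1 contribute less than an average feature.
    """
    pls = model.estimator
    T = pls.x_scores_          # (n, a)
    W = pls.x_weights_         # (p, a)
    Q = pls.y_loadings_        # (m, a)
    p, a = W.shape
    ssy = np.array([
        (T[:, i] ** 2).sum() * (Q[:, i] ** 2).sum() for i in range(a)
    ])
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn ** 2 @ ssy) / ssy.sum())
    return vip


def trim_variables(X: np.ndarray, labels: np.ndarray,
                   X_val: np.ndarray, labels_val: np.ndarray,
                   feature_names: list[str], n_components: int = 2,
                   vip_threshold: float = 1.0, max_rounds: int = 20,
                   log_transform: bool = True) -> LatentModel:
    """VIP-based backward elimination for PLS-DA.

    Each round drops every feature with VIP below the threshold and refits;
    stops when validation accuracy decreases (reverting to the previous
    model), when no feature is below threshold, or when trimming would empty
    the feature set.  The returned model's validation accuracy is therefore
    never below the untrimmed model's.
    """
    names = list(feature_names)
    keep = np.arange(len(names))
    X = np.asarray(X, float)
    X_val = np.asarray(X_val, float)
    best = fit_plsda(X, labels, X_val, labels_val, names,
                     n_components=n_components, log_transform=log_transform)
    best_acc = best.metrics.get("validation_accuracy") or 0.0
    for _ in range(max_rounds):
        vip = vip_scores(best)
        low = vip < vip_threshold * (1 - 1e-9)  # equal-VIP panels stay intact
        if not low.any():
            break
        if low.all():
            warnings.warn("trimming would drop every feature: stopping")
            break
        keep_new = keep[~low]
        cand = fit_plsda(X[:, keep_new], labels, X_val[:, keep_new], labels_val,
                         [feature_names[i] for i in keep_new],
                         n_components=min(n_components, len(keep_new)),
                         log_transform=log_transform)
        cand_acc = cand.metrics.get("validation_accuracy") or 0.0
        if cand_acc < best_acc:
            break
        keep, best, best_acc = keep_new, cand, cand_acc
    best.trimmed_features = [n for i, n in enumerate(feature_names)
                             if i not in set(keep.tolist())]
    best.metrics["n_retained"] = len(keep)
    best.extra["kept_indices"] = keep
    return best


# ---------------------------------------------------------------------------
# three-population projection space
# ---------------------------------------------------------------------------


def build_projection_space(X_by_pop: dict[str, np.ndarray],
                           feature_names: list[str],
                           time_rank: dict[str, float] | None = None,
                           n_components: int = 3,
                           log_transform: bool = True) -> LatentModel:
    """Latent space from a 3-class PLS-DA on reference populations (e.g.
    day-0 pluripotent cells and the two day-7 lineage arms).

    The reported 2-D view has deterministic, interpretable axes inside the
    latent score space: PC1 is the early-to-late (``time_rank``) centroid
    contrast, PC2 the between-arm centroid contrast orthogonalized against
    PC1 and centered on the arm midpoint, so late cells read lineage off the
    PC2 sign.  ``project`` maps any abundance matrix into (PC1, PC2).
    """
    pops = sorted(X_by_pop)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    X = np.vstack([np.asarray(X_by_pop[p], float) for p in pops])
    labels = np.concatenate([[p] * len(X_by_pop[p]) for p in pops])
    if n_components < 2:
        raise ValueError("projection space needs at least 2 components")
    base = fit_plsda(X, labels, None, None, feature_names,
                     n_components=n_components, log_transform=log_transform)
    pls = base.estimator
    prep = log_abundance if log_transform else lambda A: np.asarray(A, float)
    scores = pls.transform(prep(X))
    if time_rank is None:
        time_rank = {p: (0.0 if "pluripotent" in p.lower() else 1.0) for p in pops}
    late = [p for p in pops if time_rank[p] == max(time_rank.values())]
    early = [p for p in pops if time_rank[p] == min(time_rank.values())]
    cent = {p: scores[labels == p].mean(axis=0) for p in pops}
    # orthogonal basis of the score plane with interpretable axes: PC1 is
    # the early-to-late contrast, PC2 the between-arm contrast with the time
    # component removed (so a late cell's PC2 reads lineage, not age)
    u_time = np.mean([cent[p] for p in late], axis=0) \
        - np.mean([cent[p] for p in early], axis=0)
    u_time = u_time / max(np.linalg.norm(u_time), 1e-12)
    if len(late) >= 2:
        diff = cent[late[0]] - cent[late[1]]
    else:
        diff = np.eye(scores.shape[1])[1]
    u_fate = diff - (diff @ u_time) * u_time
    u_fate = u_fate / max(np.linalg.norm(u_fate), 1e-12)
    # center PC2 between the late-population centroids so its sign reads as
    # the lineage arm (the pluripotent population sits near the midline)
    pc2_offset = float(np.mean([cent[p] @ u_fate for p in late])) \
        if len(late) >= 2 else 0.0

    def project(Xq: np.ndarray) -> np.ndarray:
        s = pls.transform(prep(Xq))
        return np.column_stack([s @ u_time, s @ u_fate - pc2_offset])

    model = LatentModel(
        kind="PROJECTION", estimator=pls, feature_names=list(feature_names),
        scores=project(X), loadings=pls.x_loadings_,
        metrics={"populations": pops},
    )
    model.extra.update({"project": project, "labels": labels,
                        "pc2_positive_arm": late[0] if len(late) >= 2 else None})
    return model


# ---------------------------------------------------------------------------
# trajectories and group tests
# ---------------------------------------------------------------------------


def trajectory_summary(table: pd.DataFrame, feature: str,
                       covariate: np.ndarray | None = None,
                       day_col: str = "day") -> dict:
    """Per-day median and 25th/75th percentiles of one feature, plus the
    Pearson R between the per-day median vector and an external per-day
    covariate (e.g. the percentage of Oct4-positive cells)."""
    days = np.sort(table[day_col].unique())
    if len(days) < 2:
        raise ValueError("need at least 2 days")
    grouped = table.groupby(day_col)[feature]
    summary = pd.DataFrame({
        "day": days,
        "median": grouped.median().loc[days].to_numpy(),
        "q25": grouped.quantile(0.25).loc[days].to_numpy(),
        "q75": grouped.quantile(0.75).loc[days].to_numpy(),
        "n": grouped.size().loc[days].to_numpy(),
    })
    out = {"summary": summary, "R": None}
    if covariate is not None:
        covariate = np.asarray(covariate, float)
        if len(covariate) != len(days):
            raise ValueError("covariate length must match the number of days")
        med = summary["median"].to_numpy()
        if np.std(med) == 0 or np.std(covariate) == 0:
            warnings.warn("constant medians or covariate: correlation undefined")
        else:
            out["R"] = float(pearsonr(med, covariate)[0])
    return out


def compare_lineages(table: pd.DataFrame, feature: str, group_col: str,
                     group_a: str, group_b: str) -> dict:
    """Welch two-tailed t test of per-cell abundances between two lineage
    populations."""
    a = table.loc[table[group_col] == group_a, feature].to_numpy(float)
    b = table.loc[table[group_col] == group_b, feature].to_numpy(float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both groups need n >= 3")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        return {"t": 0.0, "p": 1.0, "n_a": len(a), "n_b": len(b)}
    t, p = ttest_ind(a, b, equal_var=False)
    return {"t": float(t), "p": float(p), "n_a": len(a), "n_b": len(b)}


def day_pc1_spearman(project, table: pd.DataFrame, features: list[str],
                     day_col: str = "day") -> float:
    """Spearman correlation between projection-space PC1 and the day."""
    coords = project(table[features].to_numpy(float))
    return float(spearmanr(coords[:, 0], table[day_col].to_numpy())[0])
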