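"""The multivariate model suite: phenotype labeling, PLS staging, tree
staging with class collapse, PLS-DA with VIP trimming, the bifurcation
projection space, trajectory summaries, and group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import lipidcolony as lc
from lipidcolony import cells as C, models as M


# ---------------------------------------------------------------------------
# k-means fluorescence labeling
# ---------------------------------------------------------------------------


def _two_blobs(rng, n=200, sep=4.0):
    half = n // 2
    a = np.column_stack([rng.normal(sep, 1, half), rng.normal(0, 1, half)])
    b = np.column_stack([rng.normal(0, 1, n - half), rng.normal(sep, 1, n - half)])
    X = np.vstack([a, b]) * 10 + 50
    truth = np.array(["TRA181+"] * half + ["SSEA1+"] * (n - half))
    return X, truth


def test_well_separated_blobs_labeled_correctly():
    rng = np.random.default_rng(0)
    X, truth = _two_blobs(rng)
    labels = M.label_by_kmeans(X, ("TRA181", "SSEA1"), seed=0)
    assert (labels == truth).mean() >= 0.99


def test_channel_order_swap_gives_identical_labels():
    rng = np.random.default_rng(1)
    X, _ = _two_blobs(rng)
    a = M.label_by_kmeans(X, ("TRA181", "SSEA1"), seed=0)
    b = M.label_by_kmeans(X[:, ::-1], ("SSEA1", "TRA181"), seed=0)
    assert np.array_equal(a, b)


def test_small_instance_matches_exhaustive_partition():
    rng = np.random.default_rng(2)
    X = np.vstack([rng.normal(0, 0.5, (4, 2)) + [5, 0],
                   rng.normal(0, 0.5, (4, 2)) + [0, 5]])
    labels = M.label_by_kmeans(X, ("A", "B"), seed=0)
    Z = (X - X.mean(0)) / X.std(0)
    best, best_ss = None, np.inf
    for bits in itertools.product([0, 1], repeat=7):
        lab = np.array((0,) + bits)
        if lab.sum() in (0, 8):
            continue
        ss = sum(((Z[lab == k] - Z[lab == k].mean(axis=0)) ** 2).sum()
                 for k in (0, 1))
        if ss < best_ss:
            best_ss, best = ss, lab
    as_bool = labels == labels[0]
    oracle = best == best[0]
    assert np.array_equal(as_bool, oracle)


def test_constant_channels_yield_unlabeled():
    with pytest.warns(UserWarning):
        out = M.label_by_kmeans(np.full((10, 2), 3.0), ("A", "B"))
    assert all(v is None for v in out)


# ---------------------------------------------------------------------------
# PLSR staging
# ---------------------------------------------------------------------------


def test_plsr_recovers_noiseless_linear_map():
    rng = np.random.default_rng(3)
    X = rng.normal(0, 1, (300, 3))
    y = X @ np.array([1.0, -2.0, 0.5])
    Xv = rng.normal(0, 1, (100, 3))
    yv = Xv @ np.array([1.0, -2.0, 0.5])
    m = M.fit_plsr(X, y, Xv, yv, ["a", "b", "c"], n_components=3,
                   log_transform=False)
    assert m.metrics["validation_r2"] >= 0.999


def test_plsr_null_under_label_permutation(day_series):
    _, series = day_series
    train = series.stacked()
    val = series.stacked(replicate=True)
    feats = C.feature_columns(train)
    rng = np.random.default_rng(0)
    r2s = []
    for _ in range(10):
        yperm = rng.permutation(train["day"].to_numpy())
        m = M.fit_plsr(train[feats].to_numpy(), yperm,
                       val[feats].to_numpy(), val["day"].to_numpy(), feats)
        r2s.append(m.metrics["validation_r2"])
    assert np.mean(np.array(r2s) <= 0.05) >= 0.9


def test_plsr_component_cap_enforced():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError):
        M.fit_plsr(X, np.arange(10.0), X, np.arange(10.0), list("abc"),
                   n_components=5, log_transform=False)


def test_plsr_stages_synthetic_series(day_series):
    _, series = day_series
    train, val = series.stacked(), series.stacked(replicate=True)
    feats = C.feature_columns(train)
    m = M.fit_plsr(train[feats].to_numpy(), train["day"].to_numpy(),
                   val[feats].to_numpy(), val["day"].to_numpy(), feats)
    assert m.metrics["validation_r2"] >= 0.8


# ---------------------------------------------------------------------------
# decision-tree staging
# ---------------------------------------------------------------------------


def test_tree_perfectly_separable_uses_planted_features():
    rng = np.random.default_rng(4)
    n = 400
    y = rng.integers(0, 8, n)
    X = rng.normal(0, 0.05, (n, 5))
    X[:, 1] = y // 4 + rng.normal(0, 0.01, n)   # splits {0-3} vs {4-7}
    X[:, 3] = y % 4 + rng.normal(0, 0.01, n)    # splits within halves
    m = M.fit_stage_tree(X, y, X, y, list("abcde"), min_samples_leaf=1)
    assert m.metrics["validation_accuracy_8class"] == 1.0
    imp = M.predictor_importance(m)
    assert imp["a"] + imp["c"] + imp["e"] < 1e-9


def test_tree_train_and_replicate_accuracies_agree(day_series):
    _, series = day_series
    train, val = series.stacked(), series.stacked(replicate=True)
    feats = C.feature_columns(train)
    m = M.fit_stage_tree(train[feats].to_numpy(), train["day"].to_numpy(),
                         val[feats].to_numpy(), val["day"].to_numpy(), feats)
    train_acc = (m.estimator.predict(train[feats].to_numpy())
                 == train["day"].to_numpy()).mean()
    assert abs(m.metrics["validation_accuracy_8class"] - train_acc) <= 0.10


def test_tree_null_accuracy_is_chance(day_series):
    _, series = day_series
    train, val = series.stacked(), series.stacked(replicate=True)
    feats = C.feature_columns(train)
    rng = np.random.default_rng(1)
    m = M.fit_stage_tree(train[feats].to_numpy(),
                         rng.permutation(train["day"].to_numpy()),
                         val[feats].to_numpy(), val["day"].to_numpy(), feats)
    assert abs(m.metrics["validation_accuracy_8class"] - 1 / 8) <= 0.05


def test_single_class_training_rejected():
    X = np.random.default_rng(0).normal(size=(100, 3))
    with pytest.raises(ValueError):
        M.fit_stage_tree(X, np.zeros(100, int), X, np.zeros(100, int),
                         list("abc"))


# ---------------------------------------------------------------------------
# class collapse
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("day,stage", [
    (0, "pluripotent"), (2, "pluripotent"), (3, "intermediate"),
    (5, "intermediate"), (6, "differentiated"), (7, "differentiated"),
])
def test_day_to_stage_partition(day, stage):
    assert M.stage_of_day(day) == stage


def test_day_outside_protocol_rejected():
    with pytest.raises(ValueError):
        M.stage_of_day(8)


def test_collapsing_never_reduces_accuracy():
    rng = np.random.default_rng(5)
    for _ in range(10):
        truth = rng.integers(0, 8, 200)
        pred = np.where(rng.random(200) < 0.6, truth, rng.integers(0, 8, 200))
        acc8 = (truth == pred).mean()
        _, _, acc3 = M.collapse_stages(truth, pred)
        assert acc3 >= acc8 - 1e-12


def test_importance_normalization(day_series):
    _, series = day_series
    train, val = series.stacked(), series.stacked(replicate=True)
    feats = C.feature_columns(train)
    m = M.fit_stage_tree(train[feats].to_numpy(), train["day"].to_numpy(),
                         val[feats].to_numpy(), val["day"].to_numpy(), feats)
    assert sum(M.predictor_importance(m).values()) == pytest.approx(1.0, abs=1e-9)


def test_two_equal_signals_share_importance():
    rng = np.random.default_rng(6)
    shares = []
    for trial in range(20):
        n = 600
        y = rng.integers(0, 2, n)
        X = rng.normal(0, 1, (n, 2)) + 1.5 * y[:, None]
        m = M.fit_stage_tree(X, y, X, y, ["a", "b"], min_samples_leaf=20,
                             seed=trial)
        shares.append(M.predictor_importance(m)["a"])
    assert abs(np.mean(shares) - 0.5) <= 0.10


# ---------------------------------------------------------------------------
# PLS-DA and trimming
# ---------------------------------------------------------------------------


def test_plsda_separable_classes_perfect():
    rng = np.random.default_rng(7)
    X = np.vstack([rng.normal(0, 0.3, (100, 4)) + 3,
                   rng.normal(0, 0.3, (100, 4)) - 3])
    y = np.array(["hi"] * 100 + ["lo"] * 100)
    m = M.fit_plsda(X, y, X, y, list("abcd"), log_transform=False)
    assert m.metrics["validation_accuracy"] == 1.0


def test_plsda_day6_phenotype_recovery(day_series):
    _, series = day_series
    d6tr, d6va = series.tables[6], series.replicate_tables[6]
    feats = C.feature_columns(d6tr)
    lab_tr = M.label_by_kmeans(d6tr[["tra181_mean", "ssea1_mean"]].to_numpy(),
                               ("TRA181", "SSEA1"), seed=0)
    lab_va = M.label_by_kmeans(d6va[["tra181_mean", "ssea1_mean"]].to_numpy(),
                               ("TRA181", "SSEA1"), seed=0)
    m = M.fit_plsda(d6tr[feats].to_numpy(), lab_tr,
                    d6va[feats].to_numpy(), lab_va, feats)
    assert m.metrics["validation_accuracy"] >= 0.9
    # planted loading signs: markers of each arm cluster with a common sign,
    # opposite between arms
    idx = {f: i for i, f in enumerate(feats)}
    tra_up = ["mz_742.5", "mz_778.5", "mz_861.5", "mz_863.6", "mz_940.6"]
    ssea_up = ["mz_722.5", "mz_748.5"]
    l1 = m.loadings[:, 0]
    tra_signs = {np.sign(l1[idx[f]]) for f in tra_up}
    ssea_signs = {np.sign(l1[idx[f]]) for f in ssea_up}
    assert len(tra_signs) == 1 and len(ssea_signs) == 1
    assert tra_signs != ssea_signs


def test_plsda_null_under_label_permutation(day_series):
    _, series = day_series
    d6tr, d6va = series.tables[6], series.replicate_tables[6]
    feats = C.feature_columns(d6tr)
    rng = np.random.default_rng(2)
    accs = []
    for _ in range(10):
        lab = rng.permutation(d6tr["phenotype"].to_numpy())
        m = M.fit_plsda(d6tr[feats].to_numpy(), lab, d6va[feats].to_numpy(),
                        d6va["phenotype"].to_numpy(), feats)
        accs.append(m.metrics["validation_accuracy"])
    assert abs(np.mean(accs) - 0.5) <= 0.25


def test_vip_trimming_removes_noise_keeps_signal():
    rng = np.random.default_rng(8)
    removed_frac, kept_informative = [], []
    for trial in range(20):
        n = 400
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        shift = np.where(y[:, None] == "A", 0.9, -0.9)
        X = np.hstack([rng.normal(0, 1, (n, 5)) + shift,
                       rng.normal(0, 1, (n, 50))])
        Xv = np.hstack([rng.normal(0, 1, (n, 5)) + shift,
                        rng.normal(0, 1, (n, 50))])
        names = [f"inf{i}" for i in range(5)] + [f"n{i}" for i in range(50)]
        m = M.trim_variables(X, y, Xv, y, names, log_transform=False)
        kept = {names[i] for i in m.extra["kept_indices"]}
        removed_frac.append(1 - sum(k.startswith("n") for k in kept) / 50)
        kept_informative.append(sum(k.startswith("inf") for k in kept))
    assert np.mean(removed_frac) >= 0.8
    assert min(kept_informative) == 5


def test_equal_informative_features_are_not_trimmed():
    rng = np.random.default_rng(9)
    n = 300
    y = np.array(["A"] * 150 + ["B"] * 150)
    base = np.where(y == "A", 1.0, -1.0)
    X = base[:, None] + rng.normal(0, 1e-6, (n, 6))
    m = M.trim_variables(X, y, X, y, list("abcdef"), log_transform=False)
    assert len(m.extra["kept_indices"]) == 6


def test_trimming_never_hurts_validation_accuracy(day_series):
    _, series = day_series
    d6tr, d6va = series.tables[6], series.replicate_tables[6]
    feats = C.feature_columns(d6tr)
    lab_tr = d6tr["phenotype"].to_numpy()
    lab_va = d6va["phenotype"].to_numpy()
    untrimmed = M.fit_plsda(d6tr[feats].to_numpy(), lab_tr,
                            d6va[feats].to_numpy(), lab_va, feats)
    trimmed = M.trim_variables(d6tr[feats].to_numpy(), lab_tr,
                               d6va[feats].to_numpy(), lab_va, feats)
    assert trimmed.metrics["validation_accuracy"] >= \
        untrimmed.metrics["validation_accuracy"] - 1e-12


# ---------------------------------------------------------------------------
# trimming + trim_variables VIP sanity
# ---------------------------------------------------------------------------


def test_vip_scores_mean_square_is_one(day_series):
    _, series = day_series
    d6 = series.tables[6]
    feats = C.feature_columns(d6)
    m = M.fit_plsda(d6[feats].to_numpy(), d6["phenotype"].to_numpy(),
                    None, None, feats)
    vip = M.vip_scores(m)
    assert np.mean(vip ** 2) == pytest.approx(1.0, rel=1e-6)


# ---------------------------------------------------------------------------
# projection space
# ---------------------------------------------------------------------------


def _bifurcation_pops(series):
    train = series.stacked()
    feats = C.feature_columns(train)
    d0 = train[train["day"] == 0]
    d7 = train[train["day"] == 7]
    pops = {"pluripotent_day0": d0[feats].to_numpy(),
            "NCAM1+": d7[d7["phenotype"] == "NCAM1+"][feats].to_numpy(),
            "SSEA1+": d7[d7["phenotype"] == "SSEA1+"][feats].to_numpy()}
    return train, feats, pops


def test_projection_training_populations_are_separable(bifurcation_series):
    from sklearn.metrics import silhouette_score
    _, series = bifurcation_series
    _, feats, pops = _bifurcation_pops(series)
    proj = M.build_projection_space(pops, feats)
    coords = np.vstack([proj.extra["project"](v) for v in pops.values()])
    labels = np.concatenate([[k] * len(v) for k, v in pops.items()])
    assert silhouette_score(coords, labels) > 0.2


def test_projection_pc1_tracks_day(bifurcation_series):
    _, series = bifurcation_series
    train, feats, pops = _bifurcation_pops(series)
    proj = M.build_projection_space(pops, feats)
    assert M.day_pc1_spearman(proj.extra["project"], train, feats) >= 0.7


def test_projection_pc2_separates_lineage_arms(bifurcation_series):
    _, series = bifurcation_series
    train, feats, pops = _bifurcation_pops(series)
    proj = M.build_projection_space(pops, feats)
    late = train[train["day"] >= 6]
    coords = proj.extra["project"](late[feats].to_numpy())
    ncam = late["phenotype"].to_numpy() == "NCAM1+"
    ssea = late["phenotype"].to_numpy() == "SSEA1+"
    sel = ncam | ssea
    frac = max(((coords[:, 1] > 0) == ncam)[sel].mean(),
               ((coords[:, 1] > 0) == ssea)[sel].mean())
    assert frac >= 0.9


def test_projection_needs_two_components():
    with pytest.raises(ValueError):
        M.build_projection_space(
            {"a": np.ones((5, 3)), "b": np.zeros((5, 3))},
            list("xyz"), n_components=1)


# ---------------------------------------------------------------------------
# trajectories and lineage comparison
# ---------------------------------------------------------------------------


def test_trajectory_summary_matches_percentile_oracle(day_series):
    _, series = day_series
    train = series.stacked()
    out = M.trajectory_summary(train, "mz_748.5")
    for _, row in out["summary"].iterrows():
        vals = train.loc[train["day"] == row["day"], "mz_748.5"]
        assert row["median"] == pytest.approx(vals.median())
        assert row["q25"] == pytest.approx(vals.quantile(0.25))
        assert row["q75"] == pytest.approx(vals.quantile(0.75))
        assert row["n"] == len(vals)


def test_trajectory_correlation_with_monotone_covariate():
    days = np.repeat(np.arange(8), 30)
    rng = np.random.default_rng(10)
    table = pd.DataFrame({"day": days,
                          "mz_x": days * 2.0 + rng.normal(0, 0.1, len(days))})
    cov = np.linspace(100, 30, 8)  # decreasing covariate
    out = M.trajectory_summary(table, "mz_x", covariate=cov)
    assert out["R"] < -0.9


def test_constant_feature_has_undefined_correlation():
    table = pd.DataFrame({"day": np.repeat(np.arange(8), 5),
                          "mz_x": np.ones(40)})
    with pytest.warns(UserWarning):
        out = M.trajectory_summary(table, "mz_x", covariate=np.arange(8.0))
    assert out["R"] is None


def test_planted_late_riser_anticorrelates_with_pluripotency(day_series):
    _, series = day_series
    train = series.stacked()
    out = M.trajectory_summary(train, "mz_885.5",
                               covariate=lc.OCT4_PERCENT_BY_DAY)
    assert out["R"] < -0.7


def test_lineage_comparison_identical_groups():
    rng = np.random.default_rng(11)
    table = pd.DataFrame({"grp": ["a"] * 50 + ["b"] * 50,
                          "mz_x": np.tile(rng.normal(5, 1, 50), 2)})
    res = M.compare_lineages(table, "mz_x", "grp", "a", "b")
    assert res["p"] == pytest.approx(1.0)


def test_lineage_comparison_matches_hand_computed_t():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    b = np.array([2.5, 3.5, 4.5, 5.5, 6.5])
    table = pd.DataFrame({"grp": ["a"] * 5 + ["b"] * 5,
                          "mz_x": np.concatenate([a, b])})
    res = M.compare_lineages(table, "mz_x", "grp", "a", "b")
    se = np.sqrt(a.var(ddof=1) / 5 + b.var(ddof=1) / 5)
    assert res["t"] == pytest.approx((a.mean() - b.mean()) / se)


def test_lineage_comparison_detects_planted_shift(bifurcation_series):
    _, series = bifurcation_series
    d7 = series.tables[7]
    res = M.compare_lineages(d7, "mz_748.5", "phenotype", "SSEA1+", "NCAM1+")
    assert res["t"] > 0 and res["p"] < 0.001
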