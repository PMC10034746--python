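"""Segmentation, per-cell abundance extraction, edge distances, mitosis
detection, and neighbor-relative abundances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

import lipidcolony as lc
from lipidcolony import cells as C
from lipidcolony.cells import NucleusRecord
from lipidcolony.msi import PeakFeature
from lipidcolony.transform import AffineTransform2D

IDENTITY = AffineTransform2D(0.0, 0.0, 0.0, 1.0, msi_pitch=1.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _disk_image(centers, radius_px=8, shape=(300, 300), level=100.0):
    img = np.zeros(shape)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    for (r, c) in centers:
        img[(rr - r) ** 2 + (cc - c) ** 2 <= radius_px ** 2] = level
    return img


def test_separated_disks_are_each_found():
    rng = np.random.default_rng(0)
    centers = [(r, c) for r in range(25, 300, 55) for c in range(25, 300, 55)]
    img = _disk_image(centers) + rng.normal(0, 1, (300, 300))
    recs = lc.segment_nuclei(img, pixel_size=1.0, min_area=50, max_area=500)
    assert len(recs) == len(centers)
    from scipy.spatial import cKDTree
    got = np.array([(n.centroid[1], n.centroid[0]) for n in recs])
    d, idx = cKDTree(np.asarray(centers, float)).query(got)
    assert d.max() <= 1.0
    assert len(set(idx)) == len(centers)


def test_touching_disks_are_split_by_watershed():
    img = _disk_image([(50, 50), (50, 63)], radius_px=8, shape=(100, 120))
    recs = lc.segment_nuclei(img + 0.01, pixel_size=1.0, min_area=30,
                             max_area=600, min_peak_distance_um=6.0)
    assert len(recs) == 2


def test_blank_image_yields_no_nuclei():
    with pytest.warns(UserWarning):
        recs = lc.segment_nuclei(np.zeros((50, 50)), pixel_size=1.0)
    assert recs == []


def test_phantom_nuclei_recovered_near_one_to_one(small_phantom):
    from scipy.spatial import cKDTree
    cfg, confocal, _, truth = small_phantom
    recs = lc.segment_nuclei(confocal[0].astype(float), cfg.confocal_pitch)
    assert len(recs) >= 0.85 * len(truth.cells)
    tree = cKDTree(truth.cells[["x_um", "y_um"]].to_numpy())
    d, idx = tree.query(np.array([n.centroid for n in recs]))
    matched = d < 5.0
    assert matched.mean() >= 0.95
    assert len(set(idx[matched])) >= 0.95 * matched.sum()  # 1:1, not many:1


# ---------------------------------------------------------------------------
# abundance extraction
# ---------------------------------------------------------------------------


def _manual_dataset(values_by_pixel, mz=700.0, shape=(2, 2)):
    spectra, coords = [], []
    for (r, c), v in values_by_pixel.items():
        spectra.append((np.array([mz]), np.array([float(v)])))
        coords.append((r, c))
    return lc.MSIDataset(spectra=spectra, coords=coords, shape=shape,
                         pixel_size=1.0)


FEATURE = lc.FeatureSet([PeakFeature(700.0, (699.99, 700.01), label="f")])


def test_footprint_mean_of_two_pixels():
    ds = _manual_dataset({(0, 0): 2.0, (0, 1): 4.0}, shape=(1, 2))
    contour = np.array([[-0.4, -0.4], [1.4, -0.4], [1.4, 0.4], [-0.4, 0.4]])
    rec = NucleusRecord(0, (0.5, 0.0), 1.0, 0.0, 1.0, 1.0, contour)
    table = C.extract_cell_abundances([rec], IDENTITY, ds, FEATURE)
    assert table["mz_f"].iloc[0] == pytest.approx(3.0)


def test_subpixel_nucleus_falls_back_to_centroid_pixel():
    ds = _manual_dataset({(0, 0): 2.0, (0, 1): 4.0, (1, 0): 6.0, (1, 1): 8.0})
    contour = np.array([[0.8, 0.8], [1.2, 0.8], [1.2, 1.2], [0.8, 1.2]])
    rec = NucleusRecord(0, (1.0, 1.0), 0.1, 0.0, 1.0, 1.0, contour)
    table = C.extract_cell_abundances([rec], IDENTITY, ds, FEATURE)
    assert table["mz_f"].iloc[0] == pytest.approx(8.0)


def test_nucleus_outside_grid_is_dropped():
    ds = _manual_dataset({(0, 0): 2.0}, shape=(1, 1))
    contour = np.array([[40.0, 40.0], [42.0, 40.0], [42.0, 42.0], [40.0, 42.0]])
    rec = NucleusRecord(0, (41.0, 41.0), 1.0, 0.0, 1.0, 1.0, contour)
    table = C.extract_cell_abundances([rec], IDENTITY, ds, FEATURE)
    assert len(table) == 0


def _truth_nuclei(truth):
    recs = []
    for _, row in truth.cells.iterrows():
        e, area = row["eccentricity"], row["area_um2"]
        b = np.sqrt(area * np.sqrt(1 - e ** 2) / np.pi)
        a = b / np.sqrt(1 - e ** 2)
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        o = row["orientation"]
        x = row["x_um"] + a * np.cos(th) * np.cos(o) - b * np.sin(th) * np.sin(o)
        y = row["y_um"] + a * np.cos(th) * np.sin(o) + b * np.sin(th) * np.cos(o)
        recs.append(NucleusRecord(
            int(row["cell_id"]), (row["x_um"], row["y_um"]), area, e,
            row["solidity"], row["hoechst_mean"], np.column_stack([x, y])))
    return recs


def test_extraction_matches_point_in_polygon_oracle(small_phantom):
    """Every per-nucleus abundance equals an independent shapely-based
    brute-force rasterization, exactly."""
    from shapely.geometry import Point, Polygon

    _, _, dataset, truth = small_phantom
    fs = lc.panel_featureset(truth.panel[:10])
    recs = _truth_nuclei(truth)
    table = C.extract_cell_abundances(recs, truth.transform, dataset, fs)
    images = lc.build_ion_images(dataset, fs)
    stacks = np.stack([images[f.label].values for f in fs])
    h, w = dataset.shape
    cols = [f"mz_{f.label}" for f in fs]
    for rec in recs:
        cpx = truth.transform.apply(rec.contour)
        poly = Polygon(cpx)
        r0 = max(0, int(np.floor(cpx[:, 1].min())) - 1)
        r1 = min(h - 1, int(np.ceil(cpx[:, 1].max())) + 1)
        c0 = max(0, int(np.floor(cpx[:, 0].min())) - 1)
        c1 = min(w - 1, int(np.ceil(cpx[:, 0].max())) + 1)
        pix = [(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)
               if poly.contains(Point(c, r))]
        if not pix:
            fr = int(np.floor(cpx[:, 1].mean() + 0.5))
            fc = int(np.floor(cpx[:, 0].mean() + 0.5))
            if not (0 <= fr < h and 0 <= fc < w):
                # implementation drops nuclei fully outside the MSI grid
                assert (table["cell_id"] == rec.id).sum() == 0
                continue
            pix = [(fr, fc)]
        expected = np.mean([stacks[:, r, c] for r, c in pix], axis=0)
        got = table.loc[table["cell_id"] == rec.id, cols].to_numpy().ravel()
        assert np.array_equal(got, expected)


# ---------------------------------------------------------------------------
# colony mask and edge distance
# ---------------------------------------------------------------------------


def test_edge_distance_zero_on_boundary_and_radius_at_center():
    mask = np.zeros((201, 201), bool)
    rr, cc = np.mgrid[0:201, 0:201]
    mask[(rr - 100) ** 2 + (cc - 100) ** 2 <= 100 ** 2] = True
    d = lc.edge_distance(np.array([[100.0, 0.5], [100.0, 100.0]]), mask,
                         pixel_size=1.0)
    assert d[0] <= 1.5
    assert d[1] == pytest.approx(100.0, abs=1.5)


def test_edge_distance_outside_mask_is_zero():
    mask = np.zeros((20, 20), bool)
    mask[5:15, 5:15] = True
    d = lc.edge_distance(np.array([[1.0, 1.0]]), mask, pixel_size=1.0)
    assert d[0] == 0.0


def test_edge_distance_monotone_along_inward_ray():
    mask = np.zeros((101, 101), bool)
    rr, cc = np.mgrid[0:101, 0:101]
    mask[(rr - 50) ** 2 + (cc - 50) ** 2 <= 45 ** 2] = True
    xs = np.linspace(6, 50, 20)
    d = lc.edge_distance(np.column_stack([xs, np.full(20, 50.0)]), mask, 1.0)
    assert np.all(np.diff(d) >= -1e-9)


def test_colony_mask_closing_bridges_cell_gaps():
    nuc = np.zeros((200, 200), bool)
    for r in range(40, 160, 20):
        for c in range(40, 160, 20):
            nuc[r - 3:r + 4, c - 3:c + 4] = True
    colony = lc.colony_mask_from_nuclei(nuc, pixel_size=1.0,
                                        closing_radius_um=30.0)
    assert colony[100, 100]  # interior gap filled
    assert not colony[5, 5]
    assert colony[nuc].all()  # closing is extensive


def test_planted_edge_gradient_sign_recovered(day_series):
    _, series = day_series
    table = series.tables[3]
    for label, sign in (("mz_722.5", 1), ("mz_778.5", -1)):
        r = np.corrcoef(np.log(table[label]),
                        table["edge_distance_um"])[0, 1]
        assert np.sign(r) == sign and abs(r) > 0.1


def test_edge_distance_binning_matches_groupby_oracle(day_series):
    _, series = day_series
    table = series.tables[2]
    feats = C.feature_columns(table)[:3]
    out = lc.bin_by_edge_distance(table, features=feats)
    group = np.minimum((table["edge_distance_um"] // 100).astype(int), 6)
    for g in range(7):
        sel = table[group == g]
        for f in feats:
            row = out[(out["group"] == g) & (out["feature"] == f)].iloc[0]
            if len(sel) == 0:
                assert row["n"] == 0 and np.isnan(row["mean"])
            else:
                assert row["n"] == len(sel)
                assert row["mean"] == pytest.approx(sel[f].mean())
                assert row["q25"] == pytest.approx(sel[f].quantile(0.25))
                assert row["q75"] == pytest.approx(sel[f].quantile(0.75))


def test_all_cells_at_small_distance_land_in_first_group():
    table = pd.DataFrame({
        "edge_distance_um": np.full(10, 50.0),
        "x_um": np.arange(10.0), "y_um": np.arange(10.0),
        "mz_a": np.arange(10.0),
    })
    out = lc.bin_by_edge_distance(table, features=["mz_a"])
    assert out[out["group"] == 0]["n"].iloc[0] == 10
    assert (out[out["group"] > 0]["n"] == 0).all()


# ---------------------------------------------------------------------------
# mitosis detection
# ---------------------------------------------------------------------------


def _brute_force_two_means(Z):
    """Exhaustive best 2-partition by within-cluster sum of squares."""
    n = len(Z)
    best, best_ss = None, np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        lab = np.array((0,) + bits)
        if lab.sum() in (0, n):
            continue
        ss = sum(((Z[lab == k] - Z[lab == k].mean(axis=0)) ** 2).sum()
                 for k in (0, 1))
        if ss < best_ss - 1e-12:
            best_ss, best = ss, lab
    return best


def test_mitotic_detection_accuracy_on_phantom(day_series):
    _, series = day_series
    table = series.tables[0]
    flags = lc.detect_mitotic(table, seed=0)
    assert (flags == table["mitotic"].to_numpy()).mean() >= 0.98


def test_two_means_matches_exhaustive_partition_oracle():
    rng = np.random.default_rng(5)
    for trial in range(5):
        n = 10
        Z = np.vstack([rng.normal(0, 1, (n // 2, 4)),
                       rng.normal(5, 1, (n - n // 2, 4))])
        table = pd.DataFrame(Z, columns=list(C.MITOSIS_FEATURES))
        flags = lc.detect_mitotic(table, seed=trial)
        Zs = (Z - Z.mean(0)) / Z.std(0)
        oracle = _brute_force_two_means(Zs)
        agreement = max((flags == oracle.astype(bool)).mean(),
                        (flags == ~oracle.astype(bool)).mean())
        assert agreement == 1.0


def test_mitotic_labels_invariant_to_feature_rescaling(day_series):
    _, series = day_series
    table = series.tables[0].copy()
    base = lc.detect_mitotic(table, seed=0)
    table["area_um2"] = table["area_um2"] * 37.0 + 5.0
    assert np.array_equal(lc.detect_mitotic(table, seed=0), base)


def test_degenerate_morphology_flags_nothing():
    table = pd.DataFrame({
        "area_um2": np.full(10, 80.0), "eccentricity": np.full(10, 0.5),
        "hoechst_mean": np.full(10, 100.0), "solidity": np.full(10, 0.95),
    })
    with pytest.warns(UserWarning):
        flags = lc.detect_mitotic(table, seed=0)
    assert not flags.any()


# ---------------------------------------------------------------------------
# neighbor-relative abundance
# ---------------------------------------------------------------------------


def _grid_table(n_side=15, value=5.0):
    xs, ys = np.meshgrid(np.arange(n_side) * 10.0, np.arange(n_side) * 10.0)
    return pd.DataFrame({"x_um": xs.ravel(), "y_um": ys.ravel(),
                         "mz_a": np.full(n_side ** 2, value)})


def test_constant_field_gives_exactly_zero():
    rel = C.neighbor_relative_abundance(_grid_table(), "mz_a", k_neighbors=8)
    assert np.all(rel == 0.0)


def test_single_bright_cell_reads_log_two():
    table = _grid_table()
    idx = len(table) // 2
    table.loc[idx, "mz_a"] = 10.0
    rel = C.neighbor_relative_abundance(table, "mz_a", k_neighbors=8)
    assert rel[idx] == pytest.approx(np.log(2.0), abs=1e-9)


def test_smooth_background_is_cancelled(day_series):
    cfg, _ = day_series
    flat_cfg = lc.ColonyPhantomConfig(n_cells=cfg.n_cells, seed=cfg.seed,
                                      abundance_sigma=0.0)
    table, _ = lc.generate_cell_table(flat_cfg, day=0)
    flat = next(f for f in flat_cfg.panel
                if f.shape == "flat" and f.edge_slope == 0
                and not f.lineage_mult and f.mitotic_mult == 1.0)
    rel = C.neighbor_relative_abundance(table, f"mz_{flat.label}")
    interior = table["edge_distance_um"].to_numpy() > 40
    assert (np.abs(rel[interior]) < 0.05).mean() >= 0.95


def test_k_must_be_less_than_n():
    with pytest.raises(ValueError):
        C.neighbor_relative_abundance(_grid_table(n_side=2), "mz_a",
                                      k_neighbors=4)


def test_global_rescaling_leaves_metric_unchanged(day_series):
    _, series = day_series
    table = series.tables[0].copy()
    rel = C.neighbor_relative_abundance(table, "mz_722.5")
    table["mz_722.5"] *= 1000.0
    rel2 = C.neighbor_relative_abundance(table, "mz_722.5")
    assert np.allclose(rel, rel2, atol=1e-6)


# ---------------------------------------------------------------------------
# dividing vs non-dividing comparison
# ---------------------------------------------------------------------------


def test_identical_groups_are_not_significant():
    rng = np.random.default_rng(0)
    table = _grid_table()
    table["mz_a"] = rng.lognormal(0, 0.2, len(table))
    table["mitotic"] = np.arange(len(table)) % 2 == 0
    res = C.compare_dividing(table, "mz_a", k_neighbors=8)
    assert res["p_value"] > 0.05


def test_u_statistic_equals_pairwise_count():
    table = _grid_table(n_side=4)
    rng = np.random.default_rng(1)
    table["mz_a"] = rng.lognormal(0, 0.5, len(table))
    table["mitotic"] = np.arange(len(table)) < 5
    res = C.compare_dividing(table, "mz_a", k_neighbors=6)
    rel = C.neighbor_relative_abundance(table, "mz_a", k_neighbors=6)
    div, nondiv = rel[table["mitotic"]], rel[~table["mitotic"]]
    brute = sum((a > b) + 0.5 * (a == b) for a in div for b in nondiv)
    assert res["U"] == pytest.approx(brute)


def test_planted_mitotic_lipid_enrichment_detected(day_series):
    _, series = day_series
    table = series.tables[0]
    res = C.compare_dividing(table, "mz_835.5")
    assert res["median_diff"] > 0
    assert res["p_value"] < 0.05


def test_tiny_group_yields_null_p():
    table = _grid_table()
    table["mitotic"] = False
    table.loc[:1, "mitotic"] = True
    with pytest.warns(UserWarning):
        res = C.compare_dividing(table, "mz_a", k_neighbors=8)
    assert res["p_value"] is None


def test_cell_table_csv_and_parquet_round_trip(tmp_path, day_series):
    _, series = day_series
    table = series.tables[0].head(20)
    paths = lc.save_cell_table(table, tmp_path / "cells")
    assert pd.read_csv(paths["csv"]).shape == table.shape
    assert pd.read_parquet(paths["parquet"]).equals(table.reset_index(drop=True))
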