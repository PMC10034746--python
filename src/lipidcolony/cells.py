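"""Per-cell feature extraction: nuclear segmentation, ion abundances,
colony-edge distances, mitosis detection, and neighbor-relative abundances.

Nuclei are segmented from the Hoechst channel (smooth -> Otsu ->
distance-transform watershed) and their contours are mapped into MSI pixel
space to read out a mean ion abundance per nucleus and feature.  Spatial
context comes from the colony mask (edge distance) and from the k nearest
cells (neighbor-relative log-abundance, which cancels smooth multiplicative
background unevenness such as matrix-deposition gradients).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import mannwhitneyu
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

from .msi import FeatureSet, MSIDataset, build_ion_images
from .transform import AffineTransform2D

log = logging.getLogger(__name__)

FLUOR_CHANNELS = ("TRA181", "SSEA1", "NCAM1")


@dataclass
class NucleusRecord:
    """One segmented nucleus in the confocal frame (um units)."""

    id: int
    centroid: tuple[float, float]        # (x, y) um
    area: float                          # um^2
    eccentricity: float
    solidity: float
    hoechst_mean: float
    contour: np.ndarray                  # (n, 2) of (x, y) um
    fluor_means: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def segment_nuclei(hoechst_img: np.ndarray, pixel_size: float,
                   fluor_imgs: dict[str, np.ndarray] | None = None,
                   min_area: float = 25.0, max_area: float = 400.0,
                   smooth_sigma_um: float = 1.3,
                   min_peak_distance_um: float = 4.0) -> list[NucleusRecord]:
    """Segment nuclei from a single-channel Hoechst image.

    Gaussian smoothing -> Otsu threshold -> distance-transform watershed to
    split touching nuclei -> area filter (um^2).  Per-nucleus means of any
    supplied fluorescence channels are measured under the nuclear mask.
    """
    img = np.asarray(hoechst_img, float)
    if img.size == 0 or np.ptp(img) == 0:
        warnings.warn("empty or constant image: no nuclei")
        return []
    smoothed = ndimage.gaussian_filter(img, smooth_sigma_um / pixel_size)
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed > thresh
    # drop specks well below the minimum nuclear area before watershedding
    lbl, n_obj = ndimage.label(mask)
    if n_obj:
        sizes = np.bincount(lbl.ravel())
        min_px = max(1, int(min_area / pixel_size ** 2 / 2))
        good = np.nonzero(sizes >= min_px)[0]
        mask = np.isin(lbl, good[good > 0])
    if not mask.any():
        warnings.warn("no foreground after thresholding")
        return []
    distance = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, labels=mask,
        min_distance=max(1, int(round(min_peak_distance_um / pixel_size))),
        exclude_border=False)
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = segmentation.watershed(-distance, markers, mask=mask)

    records: list[NucleusRecord] = []
    fluor_imgs = fluor_imgs or {}
    for prop in measure.regionprops(labels, intensity_image=img):
        area_um2 = prop.area * pixel_size ** 2
        if not (min_area <= area_um2 <= max_area):
            continue
        # contour of this nucleus alone, in global (x, y) um
        r0, c0, r1, c1 = prop.bbox
        patch = np.pad(labels[r0:r1, c0:c1] == prop.label, 1)
        contours = measure.find_contours(patch.astype(float), 0.5)
        if not contours:
            continue
        contour_rc = max(contours, key=len) + np.array([r0 - 1, c0 - 1])
        contour_um = contour_rc[:, ::-1] * pixel_size  # (x, y)
        cy, cx = prop.centroid
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        fluor = {name: float(im[rr, cc].mean()) for name, im in fluor_imgs.items()}
        records.append(NucleusRecord(
            id=len(records),
            centroid=(cx * pixel_size, cy * pixel_size),
            area=float(area_um2),
            eccentricity=float(prop.eccentricity),
            solidity=float(prop.solidity),
            hoechst_mean=float(prop.intensity_mean),
            contour=contour_um,
            fluor_means=fluor,
        ))
    return records


# ---------------------------------------------------------------------------
# abundance extraction
# ---------------------------------------------------------------------------


def _footprint_pixels(contour_px: np.ndarray, shape: tuple[int, int]
                      ) -> np.ndarray:
    """MSI pixel (row, col) indices whose centers fall inside the polygon;
    falls back to the single pixel containing the polygon centroid."""
    h, w = shape
    xs, ys = contour_px[:, 0], contour_px[:, 1]
    c_lo = max(0, int(np.floor(xs.min())))
    c_hi = min(w - 1, int(np.ceil(xs.max())))
    r_lo = max(0, int(np.floor(ys.min())))
    r_hi = min(h - 1, int(np.ceil(ys.max())))
    if c_hi >= c_lo and r_hi >= r_lo:
        cols, rows = np.meshgrid(np.arange(c_lo, c_hi + 1),
                                 np.arange(r_lo, r_hi + 1))
        pts = np.column_stack([cols.ravel(), rows.ravel()]).astype(float)
        inside = MplPath(contour_px).contains_points(pts)
        if inside.any():
            sel = pts[inside].astype(int)
            return np.column_stack([sel[:, 1], sel[:, 0]])  # (row, col)
    # sub-MSI-pixel nucleus: use the pixel containing the centroid
    cx, cy = contour_px[:, 0].mean(), contour_px[:, 1].mean()
    r, c = int(np.floor(cy + 0.5)), int(np.floor(cx + 0.5))
    if 0 <= r < h and 0 <= c < w:
        return np.array([[r, c]])
    return np.empty((0, 2), dtype=int)


def extract_cell_abundances(nuclei: list[NucleusRecord],
                            transform: AffineTransform2D,
                            msi_dataset: MSIDataset,
                            featureset: FeatureSet,
                            day: int | None = None,
                            condition: str | None = None) -> pd.DataFrame:
    """Build the cell-feature table: one row per nucleus, one mean-ion-
    abundance column per feature.

    Each nuclear contour is mapped into MSI pixel coordinates; the footprint
    is every pixel whose center lies inside the mapped polygon (centroid-
    pixel fallback for sub-pixel nuclei), and the abundance is the mean ion-
    image value over that footprint.  Nuclei that land fully outside the MSI
    grid are dropped (count logged).
    """
    images = build_ion_images(msi_dataset, featureset)
    stacks = np.stack([images[f.label].values for f in featureset]) \
        if len(featureset) else np.zeros((0,) + msi_dataset.shape)
    rows = []
    n_dropped = 0
    for nuc in nuclei:
        contour_px = transform.apply(nuc.contour)
        pix = _footprint_pixels(contour_px, msi_dataset.shape)
        if len(pix) == 0:
            n_dropped += 1
            continue
        abund = stacks[:, pix[:, 0], pix[:, 1]].mean(axis=1) if len(featureset) \
            else np.array([])
        row = {
            "cell_id": nuc.id,
            "x_um": nuc.centroid[0],
            "y_um": nuc.centroid[1],
            "area_um2": nuc.area,
            "eccentricity": nuc.eccentricity,
            "solidity": nuc.solidity,
            "hoechst_mean": nuc.hoechst_mean,
        }
        for ch in FLUOR_CHANNELS:
            if ch in nuc.fluor_means:
                row[f"{ch.lower()}_mean"] = nuc.fluor_means[ch]
        for f, a in zip(featureset, abund):
            row[f"mz_{f.label}"] = float(a)
        rows.append(row)
    if n_dropped:
        log.info("extract_cell_abundances: dropped %d nuclei outside MSI grid",
                 n_dropped)
    table = pd.DataFrame(rows)
    if day is not None:
        table["day"] = day
    if condition is not None:
        table["condition"] = condition
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("mz_")]


def save_cell_table(table: pd.DataFrame, stem: "str | Path") -> dict:
    """Write a cell-feature table as CSV and Parquet (``<stem>.csv`` /
    ``<stem>.parquet``)."""
    from pathlib import Path

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    csv = stem.with_suffix(".csv")
    parquet = stem.with_suffix(".parquet")
    table.to_csv(csv, index=False)
    table.to_parquet(parquet, index=False)
    return {"csv": csv, "parquet": parquet}


# ---------------------------------------------------------------------------
# colony mask and edge distance
# ---------------------------------------------------------------------------


def colony_mask_from_nuclei(nuclei_mask: np.ndarray, pixel_size: float,
                            closing_radius_um: float = 30.0) -> np.ndarray:
    """Colony footprint: morphological closing of the union of nuclear masks
    (disk radius in um), then hole filling.

    The closing is computed via two Euclidean distance transforms (dilation =
    distance-to-foreground <= r, erosion = distance-to-new-background > r),
    which is exact for disk structuring elements and fast on large images.
    """
    mask = np.asarray(nuclei_mask, bool)
    if not mask.any():
        return mask.copy()
    r = closing_radius_um / pixel_size
    dilated = ndimage.distance_transform_edt(~mask) <= r
    closed = ndimage.distance_transform_edt(dilated) > r
    return ndimage.binary_fill_holes(closed | mask)


def edge_distance(centroids_um: np.ndarray, colony_mask: np.ndarray,
                  pixel_size: float) -> np.ndarray:
    """Euclidean distance (um) from each centroid to the colony boundary:
    the distance transform of the mask sampled at the centroid.  Centroids
    outside the mask get 0 (flagged via a warning count)."""
    dist_px = ndimage.distance_transform_edt(np.asarray(colony_mask, bool))
    pts = np.atleast_2d(np.asarray(centroids_um, float)) / pixel_size
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, colony_mask.shape[0] - 1)
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, colony_mask.shape[1] - 1)
    d = dist_px[rows, cols] * pixel_size
    outside = ~np.asarray(colony_mask, bool)[rows, cols]
    if outside.any():
        log.info("edge_distance: %d centroid(s) outside the colony mask -> 0",
                 int(outside.sum()))
        d = np.where(outside, 0.0, d)
    return d


def bin_by_edge_distance(table: pd.DataFrame, n_groups: int = 7,
                         bin_width: float = 100.0,
                         features: list[str] | None = None) -> pd.DataFrame:
    """Per-group summaries of ion abundance versus distance from the colony
    edge: groups [0, w), [w, 2w), ..., last group open-ended; per group and
    feature the mean, 25th/75th percentiles, and n."""
    if "edge_distance_um" not in table.columns:
        raise ValueError("table lacks edge_distance_um; run edge_distance first")
    features = features if features is not None else feature_columns(table)
    edges = np.arange(n_groups) * bin_width
    group = np.minimum(
        (table["edge_distance_um"].to_numpy() // bin_width).astype(int),
        n_groups - 1)
    out = []
    for g in range(n_groups):
        sel = table.loc[group == g, features]
        n = len(sel)
        for f in features:
            vals = sel[f]
            out.append({
                "group": g,
                "distance_lo_um": edges[g],
                "distance_hi_um": np.inf if g == n_groups - 1 else edges[g] + bin_width,
                "feature": f,
                "n": n,
                "mean": float(vals.mean()) if n else np.nan,
                "q25": float(vals.quantile(0.25)) if n else np.nan,
                "q75": float(vals.quantile(0.75)) if n else np.nan,
            })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# mitosis detection
# ---------------------------------------------------------------------------

MITOSIS_FEATURES = ("area_um2", "eccentricity", "hoechst_mean", "solidity")


def detect_mitotic(table: pd.DataFrame, seed: int = 0, k: int = 2) -> np.ndarray:
    """Flag mitotic cells by 2-means clustering of standardized nuclear
    morphology + Hoechst brightness.

    Mitotic chromatin condenses: the mitotic cluster is the one scoring
    higher on mean standardized Hoechst brightness minus mean standardized
    area.  Deterministic for a fixed seed; all-identical features yield
    all-non-mitotic with a warning.
    """
    X = table.loc[:, list(MITOSIS_FEATURES)].to_numpy(float)
    if len(X) < 2 * k:
        raise ValueError(f"need at least {2 * k} nuclei")
    scales = X.std(axis=0)
    scales = np.where(scales <= 1e-9 * (np.abs(X).mean(axis=0) + 1.0),
                      0.0, scales)
    if np.all(scales == 0):
        warnings.warn("degenerate morphology features: no mitotic cells flagged")
        return np.zeros(len(X), dtype=bool)
    Z = StandardScaler().fit_transform(X[:, scales > 0])
    kept = [f for f, s in zip(MITOSIS_FEATURES, scales) if s > 0]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(Z)
    lab = km.labels_
    score = np.full(k, -np.inf)
    for c in range(k):
        m = Z[lab == c].mean(axis=0)
        s = 0.0
        if "hoechst_mean" in kept:
            s += m[kept.index("hoechst_mean")]
        if "area_um2" in kept:
            s -= m[kept.index("area_um2")]
        score[c] = s
    mitotic_cluster = int(np.argmax(score))
    return lab == mitotic_cluster


# ---------------------------------------------------------------------------
# neighbor-relative abundance
# ---------------------------------------------------------------------------


def neighbor_relative_abundance(table: pd.DataFrame, feature: str,
                                k_neighbors: int = 20,
                                eps: float = 1e-9) -> np.ndarray:
    """Log-ratio of a cell's abundance to the median abundance of its k
    nearest neighbors (by centroid distance):

        v_i = log(a_i + eps) - median_j(log(a_j + eps))

    Cancels smooth multiplicative background fields and is invariant to
    global rescaling of the abundances.
    """
    n = len(table)
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of cells")
    pts = table[["x_um", "y_um"]].to_numpy(float)
    a = np.log(table[feature].to_numpy(float) + eps)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k_neighbors + 1)
    idx = np.atleast_2d(idx)[:, 1:]  # drop self
    return a - np.median(a[idx], axis=1)


def compare_dividing(table: pd.DataFrame, feature: str,
                     mitotic_col: str = "mitotic",
                     k_neighbors: int = 20) -> dict:
    """Median difference (dividing minus non-dividing) of neighbor-relative
    abundances, with a two-sided Mann-Whitney U p-value."""
    flags = table[mitotic_col].to_numpy(bool)
    rel = neighbor_relative_abundance(table, feature, k_neighbors=k_neighbors)
    div, nondiv = rel[flags], rel[~flags]
    if len(div) == 0 or len(nondiv) == 0:
        raise ValueError("both dividing and non-dividing groups must be non-empty")
    median_diff = float(np.median(div) - np.median(nondiv))
    if min(len(div), len(nondiv)) < 3:
        warnings.warn("group with n < 3: p-value not computed")
        return {"median_diff": median_diff, "p_value": None,
                "n_dividing": len(div), "n_nondividing": len(nondiv)}
    stat, p = mannwhitneyu(div, nondiv, alternative="two-sided")
    return {"median_diff": median_diff, "p_value": float(p), "U": float(stat),
            "n_dividing": len(div), "n_nondividing": len(nondiv)}
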