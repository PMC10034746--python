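"""Synthetic colony phantoms: paired confocal + MSI data with full ground truth.

The generator emulates a staggered spontaneous-differentiation experiment:
eight colony samples (day 0-7), each an irregular star-convex colony of
non-overlapping elliptical nuclei.  Every cell carries a true phenotype
(pluripotent / TRA181+ / SSEA1+ / NCAM1+, mixed by day and condition), a
true mitotic flag (condensed, bright nuclei), a true edge distance, and a
true expected abundance for each of ~70 m/z features.  Expected abundances
factor as

    base * trajectory(day) * lineage multiplier * edge gradient * background

with lognormal measurement noise on top.  Day trajectories follow four
qualitative shapes (stable growth, rise-then-fall, flat-then-rise, rapid
early decline); the smooth multiplicative background field emulates uneven
matrix deposition.  Imaging mode renders a 4-channel confocal stack and an
MSI pixel grid related by a known affine transform; table mode skips
rendering and emits the cell-feature table directly (fast path for model
-level work).  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .msi import MSIDataset, FeatureSet, PeakFeature
from .transform import AffineTransform2D

PHENOTYPES = ("pluripotent", "TRA181+", "SSEA1+", "NCAM1+")
CONDITIONS = ("control", "LY294002_35uM", "LY294002_100uM", "DZA_50uM")

#: per-day percentage of Oct4-positive cells (flow-cytometry style covariate,
#: consumed as a given vector by trajectory summaries and reports)
OCT4_PERCENT_BY_DAY = np.array([95.0, 93.0, 90.0, 82.0, 70.0, 55.0, 35.0, 20.0])

TRAJECTORY_SHAPES = ("increasing", "rise_fall", "flat_then_rise",
                     "rapid_decline", "flat")


def trajectory(shape: str, day: float) -> float:
    """Day-dependent abundance multiplier for one qualitative shape."""
    d = float(day)
    if shape == "increasing":
        return 0.5 + 1.5 * d / 7.0
    if shape == "rise_fall":
        return 0.7 + 0.9 * np.exp(-(((d - 2.0) / 1.8) ** 2))
    if shape == "flat_then_rise":
        return 0.8 if d <= 4 else 0.8 + 1.2 * (d - 4.0) / 3.0
    if shape == "rapid_decline":
        return 2.0 * np.exp(-1.2 * d)
    if shape == "flat":
        return 1.0
    raise ValueError(f"unknown trajectory shape {shape!r}")


@dataclass(frozen=True)
class FeaturePlan:
    """Ground-truth recipe for one m/z feature."""

    mz: float
    shape: str = "flat"
    base: float = 100.0
    annotation: str | None = None
    lineage_mult: dict = field(default_factory=dict)  # phenotype -> multiplier
    edge_slope: float = 0.0      # + = more abundant deeper in the colony
    mitotic_mult: float = 1.0
    colony_associated: bool = True

    @property
    def label(self) -> str:
        return f"{self.mz:.1f}"


_LINEAGE_UP = 1.8  # multiplier for a lineage-enriched feature


def default_panel(n_features: int = 70, panel_seed: int = 20230) -> list[FeaturePlan]:
    """The default ~70-feature panel.

    Anchor features mirror the qualitative behaviour of well-characterized
    phospholipid ions (stable growth for the differentiation-associated PE
    ether species, early rapid decline for the unannotated 940.6 species,
    late rise for PI 38:4, rise-fall for the PE/PI cluster), with lineage
    enrichments matching the planted phenotype signatures and edge-distance
    gradients of either sign.  Remaining features are filler with assorted
    shapes or day-flat behaviour.
    """
    up = _LINEAGE_UP
    anchors = [
        FeaturePlan(722.51, "increasing", 120.0, "PC 32:0",
                    {"SSEA1+": up}, edge_slope=0.8),
        FeaturePlan(748.52, "increasing", 150.0, "PE O-38:6",
                    {"SSEA1+": up}, edge_slope=0.8),
        FeaturePlan(742.54, "rise_fall", 110.0, "PE 36:2",
                    {"TRA181+": up}),
        FeaturePlan(778.53, "rise_fall", 130.0, "PE 38:4",
                    {"TRA181+": up, "NCAM1+": up}, edge_slope=-0.8),
        FeaturePlan(819.52, "increasing", 80.0, None, {"SSEA1+": up}),
        FeaturePlan(821.54, "increasing", 80.0, None, {"SSEA1+": up}),
        FeaturePlan(835.53, "rise_fall", 90.0, "PI 34:1",
                    {"TRA181+": up}, mitotic_mult=1.6),
        FeaturePlan(859.54, "rise_fall", 85.0, "PI 36:3", {"NCAM1+": up}),
        FeaturePlan(861.55, "rise_fall", 100.0, "PI 36:2",
                    {"TRA181+": up, "NCAM1+": up}, mitotic_mult=1.6),
        FeaturePlan(863.56, "rise_fall", 100.0, "PI 36:1",
                    {"TRA181+": up, "NCAM1+": up}, mitotic_mult=1.6),
        FeaturePlan(883.55, "rise_fall", 75.0, "PI 38:5", {"NCAM1+": up}),
        FeaturePlan(885.55, "flat_then_rise", 140.0, "PI 38:4",
                    {"NCAM1+": up}),
        FeaturePlan(940.60, "rapid_decline", 90.0, None,
                    {"TRA181+": up, "NCAM1+": up},
                    edge_slope=-0.8, mitotic_mult=1.6),
    ]
    rng = np.random.default_rng(panel_seed)
    taken = np.array([a.mz for a in anchors])
    filler_shapes = ["increasing", "rise_fall", "flat_then_rise",
                     "rapid_decline", "flat", "flat"]
    fillers: list[FeaturePlan] = []
    while len(anchors) + len(fillers) < n_features:
        mz = float(np.round(rng.uniform(250.0, 1580.0), 3))
        if np.min(np.abs(taken - mz)) < 0.5:
            continue
        taken = np.append(taken, mz)
        shape = filler_shapes[len(fillers) % len(filler_shapes)]
        base = float(np.round(rng.lognormal(np.log(60.0), 0.5), 1))
        fillers.append(FeaturePlan(mz, shape, base))
    panel = sorted(anchors + fillers, key=lambda f: f.mz)
    return panel


def panel_featureset(panel: list[FeaturePlan]) -> FeatureSet:
    """The FeatureSet a perfect peak-picking run would recover."""
    return FeatureSet([
        PeakFeature(center_mz=f.mz, interval=(f.mz - 0.010, f.mz + 0.010),
                    annotation=f.annotation)
        for f in panel
    ])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ColonyPhantomConfig:
    n_cells: int = 2000
    days: tuple = tuple(range(8))
    condition: str = "control"
    confocal_pitch: float = 0.65       # um/px
    msi_pitch: float = 10.0            # um/px (25 for FTICR-style runs)
    panel: list[FeaturePlan] = field(default_factory=default_panel)
    mitotic_fraction: float = 0.05
    abundance_sigma: float = 0.4       # lognormal sigma on abundances
    fluor_sigma: float = 15.0          # gaussian sigma on fluorescence (a.u.)
    background_amplitude: float = 0.25
    background_length_um: float = 150.0
    mass_jitter_mda: float = 3.0       # clipped at +-8 mDa (stays in-bin)
    cell_spacing_um: float = 13.0
    boundary_irregularity: float = 0.15
    margin_um: float = 60.0
    edge_gradient_range_um: float = 300.0
    # true confocal->MSI transform: sampled within these half-ranges unless
    # an explicit transform is supplied
    true_rotation_deg: float = 5.0
    true_shift_um: float = 150.0
    true_scale: float = 0.02
    true_transform: AffineTransform2D | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.confocal_pitch <= 0 or self.msi_pitch <= 0:
            raise ValueError("pitches must be > 0")

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["days"] = list(self.days)
        d["panel"] = [asdict(f) for f in self.panel]
        d["true_transform"] = (self.true_transform.to_dict()
                               if self.true_transform else None)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ColonyPhantomConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        d["days"] = tuple(d["days"])
        d["panel"] = [FeaturePlan(**f) for f in d["panel"]]
        if d.get("true_transform"):
            d["true_transform"] = AffineTransform2D.from_dict(d["true_transform"])
        return cls(**d)

    @property
    def colony_radius_um(self) -> float:
        site_area = self.cell_spacing_um ** 2 * np.sqrt(3) / 2
        return float(np.sqrt(self.n_cells * site_area * 1.3 / np.pi))

    @property
    def field_um(self) -> float:
        return 2 * (self.colony_radius_um + self.margin_um)


@dataclass
class GroundTruth:
    """Per-cell and global planted truth for one generated colony."""

    cells: pd.DataFrame                     # x/y um, phenotype, mitotic, edge distance
    expected: pd.DataFrame                  # per-cell expected abundance (mz_* columns)
    transform: AffineTransform2D
    colony_polygon: np.ndarray              # (n, 2) um, confocal frame
    panel: list[FeaturePlan]
    colony_mask: np.ndarray | None = None   # MSI grid
    feature_fields: dict | None = None      # label -> expected MSI pixel field


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _boundary_radius_fn(rng: np.random.Generator, r0: float, irregularity: float,
                        n_harmonics: int = 5):
    ks = np.arange(2, 2 + n_harmonics)
    amps = rng.uniform(-irregularity, irregularity, size=n_harmonics) / np.sqrt(ks - 1)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)

    def radius(theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, float)
        mod = 1.0 + sum(a * np.cos(k * theta + p)
                        for a, k, p in zip(amps, ks, phases))
        return r0 * np.clip(mod, 0.5, 1.5)

    return radius


def _place_cells(rng: np.random.Generator, radius_fn, n_cells: int,
                 spacing: float, inset: float = 6.0) -> np.ndarray:
    """Jittered hexagonal packing inside the colony boundary (colony-centered
    um coordinates)."""
    r_max = float(radius_fn(np.linspace(0, 2 * np.pi, 256)).max())
    xs = np.arange(-r_max, r_max + spacing, spacing)
    ys = np.arange(-r_max, r_max + spacing * np.sqrt(3) / 2,
                   spacing * np.sqrt(3) / 2)
    gx, gy = np.meshgrid(xs, ys)
    gx[1::2] += spacing / 2
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts + rng.uniform(-0.28 * spacing, 0.28 * spacing, size=pts.shape)
    r = np.hypot(pts[:, 0], pts[:, 1])
    theta = np.arctan2(pts[:, 1], pts[:, 0])
    inside = r < radius_fn(theta) - inset
    candidates = pts[inside]
    if len(candidates) < n_cells:
        max_density = len(candidates)
        raise ValueError(
            f"cannot place {n_cells} cells without overlap; at spacing "
            f"{spacing} um this colony fits at most {max_density} cells")
    idx = rng.choice(len(candidates), size=n_cells, replace=False)
    return candidates[np.sort(idx)]


def _edge_distance_truth(points: np.ndarray, radius_fn,
                         grid_um: float = 4.0) -> np.ndarray:
    """True edge distance via a fine-grid distance transform of the colony
    footprint (colony-centered coordinates)."""
    r_max = float(radius_fn(np.linspace(0, 2 * np.pi, 256)).max()) + 2 * grid_um
    ax = np.arange(-r_max, r_max + grid_um, grid_um)
    gx, gy = np.meshgrid(ax, ax)
    r = np.hypot(gx, gy)
    th = np.arctan2(gy, gx)
    mask = r < radius_fn(th)
    dist = ndimage.distance_transform_edt(mask) * grid_um
    cols = (points[:, 0] - ax[0]) / grid_um
    rows = (points[:, 1] - ax[0]) / grid_um
    return ndimage.map_coordinates(dist, [rows, cols], order=1, mode="nearest")


def _background_field(rng: np.random.Generator, field_um: float,
                      length_um: float, amplitude: float,
                      grid_um: float = 10.0):
    """Smooth multiplicative background: exp(amplitude * smoothed white
    noise), unit mean log, sampled bilinearly at query points (field-frame
    um coordinates)."""
    n = int(np.ceil(field_um / grid_um)) + 4
    white = rng.standard_normal((n, n))
    smooth = ndimage.gaussian_filter(white, length_um / grid_um, mode="reflect")
    smooth = (smooth - smooth.mean()) / max(smooth.std(), 1e-12)
    logbg = amplitude * smooth

    def sample(points_um: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points_um) / grid_um
        return np.exp(ndimage.map_coordinates(
            logbg, [pts[:, 1], pts[:, 0]], order=1, mode="nearest"))

    return sample


# ---------------------------------------------------------------------------
# phenotype mixtures
# ---------------------------------------------------------------------------


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def phenotype_probabilities(day: int, condition: str) -> dict[str, float]:
    """Day/condition-dependent phenotype mixture.

    Day 0 is entirely pluripotent in every condition.  Control colonies
    trade TRA181+ for SSEA1+ over time and never express NCAM1; PI3K
    inhibition adds a dose-dependent NCAM1+ arm (at the high dose the late
    days are a pure SSEA1+/NCAM1+ bifurcation, reaching a 50/50 split at
    day 7); PEMT inhibition delays the pluripotency loss.
    """
    if day == 0:
        return {"pluripotent": 1.0}
    if condition == "control":
        p_ssea = _sigmoid((day - 4.0) / 1.1)
        return {"SSEA1+": p_ssea, "TRA181+": 1.0 - p_ssea}
    if condition == "DZA_50uM":
        p_ssea = _sigmoid((day - 6.0) / 1.1)
        return {"SSEA1+": p_ssea, "TRA181+": 1.0 - p_ssea}
    if condition == "LY294002_35uM":
        q = 0.25 * _sigmoid((day - 4.5))
        p_ssea = (1 - q) * _sigmoid((day - 4.0) / 1.1)
        return {"NCAM1+": q, "SSEA1+": p_ssea, "TRA181+": 1.0 - q - p_ssea}
    # LY294002_100uM
    if day >= 5:
        q = {5: 0.35, 6: 0.45, 7: 0.50}[min(day, 7)]
        return {"NCAM1+": q, "SSEA1+": 1.0 - q}
    q = 0.30 * _sigmoid(day - 3.0)
    p_ssea = (1 - q) * _sigmoid((day - 4.0) / 1.1)
    return {"NCAM1+": q, "SSEA1+": p_ssea, "TRA181+": 1.0 - q - p_ssea}


def _assign_phenotypes(rng: np.random.Generator, points: np.ndarray,
                       day: int, condition: str,
                       cluster_scale_cells: int = 80) -> np.ndarray:
    """Sample phenotypes from the day mixture; the NCAM1+ quota is filled by
    proximity to seeded cluster centers (Matern-style spatial clustering)."""
    n = len(points)
    probs = phenotype_probabilities(day, condition)
    phenos = np.array(
        rng.choice(list(probs), size=n, p=np.array(list(probs.values()))),
        dtype=object)
    n_ncam = int((phenos == "NCAM1+").sum())
    if n_ncam > 0:
        # re-assign the NCAM1 quota spatially instead of uniformly
        base = np.where(phenos == "NCAM1+", "SSEA1+", phenos).astype(object)
        n_clusters = max(1, int(round(n_ncam / cluster_scale_cells)))
        centers = points[rng.choice(n, size=n_clusters, replace=False)]
        d = np.min(np.linalg.norm(
            points[:, None, :] - centers[None, :, :], axis=2), axis=1)
        order = np.argsort(d, kind="stable")
        base[order[:n_ncam]] = "NCAM1+"
        phenos = base
    return phenos


# ---------------------------------------------------------------------------
# cell-level generation (shared by table and imaging modes)
# ---------------------------------------------------------------------------


def _rng(config: ColonyPhantomConfig, day: int, stream: int,
         replicate: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, day, stream, replicate])


_STRUCTURE, _NOISE, _IMAGING = 0, 1, 2


def _sample_true_transform(config: ColonyPhantomConfig, day: int,
                           msi_shape: tuple[int, int]) -> AffineTransform2D:
    if config.true_transform is not None:
        return config.true_transform
    rng = _rng(config, day, 9)
    f = config.field_um
    return AffineTransform2D(
        rotation_deg=float(rng.uniform(-config.true_rotation_deg,
                                       config.true_rotation_deg)),
        dx_um=float(rng.uniform(-config.true_shift_um, config.true_shift_um)),
        dy_um=float(rng.uniform(-config.true_shift_um, config.true_shift_um)),
        scale=float(1.0 + rng.uniform(-config.true_scale, config.true_scale)),
        msi_pitch=config.msi_pitch,
        center_conf_um=(f / 2, f / 2),
        center_msi_px=((msi_shape[1] - 1) / 2.0, (msi_shape[0] - 1) / 2.0),
    )


def _msi_shape(config: ColonyPhantomConfig) -> tuple[int, int]:
    n = int(np.ceil(config.field_um / config.msi_pitch)) + 12
    return (n, n)


def _generate_cells(config: ColonyPhantomConfig, day: int) -> tuple[pd.DataFrame, np.ndarray, object]:
    """Structural truth for one colony: positions, phenotypes, morphology,
    edge distance (deterministic; shared by primary and replicate)."""
    rng = _rng(config, day, _STRUCTURE)
    radius_fn = _boundary_radius_fn(rng, config.colony_radius_um,
                                    config.boundary_irregularity)
    pts = _place_cells(rng, radius_fn, config.n_cells, config.cell_spacing_um)
    edge = _edge_distance_truth(pts, radius_fn)
    phenos = _assign_phenotypes(rng, pts, day, config.condition)
    n = len(pts)
    mitotic = rng.random(n) < config.mitotic_fraction
    area = np.clip(rng.normal(78.0, 12.0, n), 40.0, 150.0)
    area[mitotic] *= 0.55
    ecc = np.where(mitotic, rng.uniform(0.65, 0.85, n), rng.uniform(0.30, 0.60, n))
    solidity = np.clip(np.where(mitotic, rng.normal(0.95, 0.015, n),
                                rng.normal(0.975, 0.01, n)), 0.8, 1.0)
    hoechst = 120.0 * np.where(mitotic, 2.2, 1.0) * (1 + 0.08 * rng.standard_normal(n))
    orientation = rng.uniform(0, np.pi, n)
    shift = config.field_um / 2
    cells = pd.DataFrame({
        "cell_id": np.arange(n),
        "x_um": pts[:, 0] + shift,
        "y_um": pts[:, 1] + shift,
        "phenotype": phenos,
        "mitotic": mitotic,
        "edge_distance_um": edge,
        "area_um2": area,
        "eccentricity": ecc,
        "solidity": solidity,
        "hoechst_mean": hoechst,
        "orientation": orientation,
        "day": day,
        "condition": config.condition,
    })
    theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    polygon = np.column_stack([
        radius_fn(theta) * np.cos(theta) + shift,
        radius_fn(theta) * np.sin(theta) + shift,
    ])
    return cells, polygon, radius_fn


def _expected_abundances(config: ColonyPhantomConfig, cells: pd.DataFrame,
                         day: int) -> pd.DataFrame:
    """Per-cell expected abundance for each panel feature (no noise)."""
    bg = _background_field(_rng(config, day, 3), config.field_um,
                           config.background_length_um,
                           config.background_amplitude)
    bgv = bg(cells[["x_um", "y_um"]].to_numpy())
    d_norm = np.clip(cells["edge_distance_um"].to_numpy()
                     / config.edge_gradient_range_um, 0.0, 1.0) - 0.5
    phen = cells["phenotype"].to_numpy()
    mito = cells["mitotic"].to_numpy(bool)
    out = {}
    for f in config.panel:
        if not f.colony_associated:
            continue
        v = f.base * trajectory(f.shape, day) * np.ones(len(cells))
        lin = np.array([f.lineage_mult.get(p, 1.0) for p in phen])
        v = v * lin * (1.0 + f.edge_slope * d_norm)
        if f.mitotic_mult != 1.0:
            v = v * np.where(mito, f.mitotic_mult, 1.0)
        out[f"mz_{f.label}"] = v * bgv
    return pd.DataFrame(out, index=cells.index)


def _fluorescence(config: ColonyPhantomConfig, cells: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Marker fluorescence truth: a cell is bright in the channel matching
    its phenotype (pluripotent cells are TRA-1-81 bright)."""
    n = len(cells)
    high, low = 180.0, 35.0
    phen = cells["phenotype"].to_numpy()
    vals = {}
    for ch, positive in (("tra181", ("TRA181+", "pluripotent")),
                         ("ssea1", ("SSEA1+",)),
                         ("ncam1", ("NCAM1+",))):
        base = np.where(np.isin(phen, positive), high, low)
        vals[f"{ch}_mean"] = np.clip(
            base + config.fluor_sigma * rng.standard_normal(n), 0.0, None)
    return pd.DataFrame(vals, index=cells.index)


def generate_cell_table(config: ColonyPhantomConfig, day: int,
                        replicate: int = 0) -> tuple[pd.DataFrame, GroundTruth]:
    """Fast path: the cell-feature table a perfect extraction would produce,
    with lognormal measurement noise on the planted expected abundances.

    ``replicate`` selects an independent noise realization over the same
    expected abundances (the biological-replicate validation convention).
    """
    cells, polygon, _ = _generate_cells(config, day)
    expected = _expected_abundances(config, cells, day)
    rng = _rng(config, day, _NOISE, replicate)
    noise = np.exp(config.abundance_sigma
                   * rng.standard_normal(expected.shape))
    observed = expected * noise
    fluor = _fluorescence(config, cells, rng)
    table = pd.concat([
        cells.drop(columns=["orientation"]), fluor, observed
    ], axis=1)
    msi_shape = _msi_shape(config)
    truth = GroundTruth(
        cells=cells, expected=expected,
        transform=_sample_true_transform(config, day, msi_shape),
        colony_polygon=polygon, panel=list(config.panel),
    )
    return table, truth


# ---------------------------------------------------------------------------
# imaging mode
# ---------------------------------------------------------------------------


def _render_confocal(config: ColonyPhantomConfig, cells: pd.DataFrame,
                     fluor: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """4-channel confocal stack (Hoechst, TRA181, SSEA1, NCAM1) at the
    confocal pitch."""
    from skimage.draw import ellipse

    px = config.confocal_pitch
    n_px = int(np.ceil(config.field_um / px))
    img = np.zeros((4, n_px, n_px), dtype=float)
    area = cells["area_um2"].to_numpy()
    ecc = cells["eccentricity"].to_numpy()
    b_ax = np.sqrt(area * np.sqrt(1 - ecc ** 2) / np.pi)   # minor semi-axis um
    a_ax = b_ax / np.sqrt(1 - ecc ** 2)                    # major semi-axis um
    levels = np.column_stack([
        cells["hoechst_mean"].to_numpy(),
        fluor["tra181_mean"].to_numpy(),
        fluor["ssea1_mean"].to_numpy(),
        fluor["ncam1_mean"].to_numpy(),
    ])
    for i in range(len(cells)):
        rr, cc = ellipse(cells["y_um"].iat[i] / px, cells["x_um"].iat[i] / px,
                         a_ax[i] / px, b_ax[i] / px,
                         shape=(n_px, n_px),
                         rotation=cells["orientation"].iat[i])
        img[:, rr, cc] = levels[i][:, None]
    for c in range(4):
        img[c] = ndimage.gaussian_filter(img[c], 1.0)
    img += np.abs(rng.normal(0.0, 2.0, size=img.shape))
    return img.astype(np.float32)


MATRIX_PEAKS = ((333.114, 6.0), (255.233, 4.0))  # matrix cluster ions
DETECTION_FLOOR = 0.5  # centroids below this intensity are not emitted


def _synthesize_msi(config: ColonyPhantomConfig, cells: pd.DataFrame,
                    expected: pd.DataFrame, transform: AffineTransform2D,
                    polygon: np.ndarray, rng: np.random.Generator
                    ) -> tuple[MSIDataset, np.ndarray, dict]:
    """Deposit per-cell expected abundances onto the MSI grid and emit
    centroid spectra with mass jitter plus colony-independent matrix peaks."""
    from matplotlib.path import Path as MplPath

    shape = _msi_shape(config)
    h, w = shape
    feats = [f for f in config.panel if f.colony_associated]
    labels = [f.label for f in feats]
    pos_px = transform.apply(cells[["x_um", "y_um"]].to_numpy())
    cols = np.clip(np.round(pos_px[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(pos_px[:, 1]).astype(int), 0, h - 1)
    flat = rows * w + cols
    noisy = expected.to_numpy() * np.exp(
        config.abundance_sigma * rng.standard_normal(expected.shape))
    field = np.zeros((h * w, len(feats)))
    np.add.at(field, flat, noisy[:, [expected.columns.get_loc(f"mz_{l}")
                                     for l in labels]])
    # a cell's lipid footprint (whole cell + laser spot) is wider than its
    # nucleus: spread each deposit over ~1 pixel radius so the colony
    # interior is contiguous at the MSI pitch
    field = field.T.reshape(len(feats), h, w)
    for i in range(len(feats)):
        field[i] = ndimage.gaussian_filter(field[i], 1.1)

    centers = np.array([f.mz for f in feats])
    jitter_clip = 0.008
    spectra = []
    coords = []
    pixel_noise = np.exp(0.1 * rng.standard_normal((h, w, len(feats))))
    jitter = np.clip(rng.normal(0.0, config.mass_jitter_mda * 1e-3,
                                size=(h, w, len(feats))),
                     -jitter_clip, jitter_clip)
    matrix_int = 1.0 + 0.1 * rng.standard_normal((h, w, len(MATRIX_PEAKS)))
    for r in range(h):
        for c in range(w):
            vals = field[:, r, c] * pixel_noise[r, c]
            keep = vals > DETECTION_FLOOR
            mz = centers[keep] + jitter[r, c, keep]
            inten = vals[keep]
            for k, (pmz, pint) in enumerate(MATRIX_PEAKS):
                mz = np.append(mz, pmz)
                inten = np.append(inten, max(pint * matrix_int[r, c, k],
                                             DETECTION_FLOOR))
            order = np.argsort(mz)
            spectra.append((mz[order], inten[order]))
            coords.append((r, c))
    dataset = MSIDataset(
        spectra=spectra, coords=np.array(coords), shape=shape,
        pixel_size=config.msi_pitch, mz_range=(200.0, 1600.0), mode="centroid")
    poly_px = transform.apply(polygon)
    gx, gy = np.meshgrid(np.arange(w), np.arange(h))
    inside = MplPath(poly_px).contains_points(
        np.column_stack([gx.ravel(), gy.ravel()]))
    colony_mask = inside.reshape(h, w)
    fields = {l: field[i] for i, l in enumerate(labels)}
    return dataset, colony_mask, fields


def generate_colony(config: ColonyPhantomConfig, day: int, replicate: int = 0
                    ) -> tuple[np.ndarray, MSIDataset, GroundTruth]:
    """Full imaging phantom for one day: (4-channel confocal stack,
    MSIDataset, GroundTruth).  Byte-deterministic given config.seed."""
    cells, polygon, _ = _generate_cells(config, day)
    expected = _expected_abundances(config, cells, day)
    msi_shape = _msi_shape(config)
    transform = _sample_true_transform(config, day, msi_shape)
    rng_noise = _rng(config, day, _NOISE, replicate)
    fluor = _fluorescence(config, cells, rng_noise)
    rng_img = _rng(config, day, _IMAGING, replicate)
    confocal = _render_confocal(config, cells, fluor, rng_img)
    dataset, colony_mask, fields = _synthesize_msi(
        config, cells, expected, transform, polygon, rng_img)
    truth = GroundTruth(
        cells=cells, expected=expected, transform=transform,
        colony_polygon=polygon, panel=list(config.panel),
        colony_mask=colony_mask, feature_fields=fields,
    )
    return confocal, dataset, truth


# ---------------------------------------------------------------------------
# day series
# ---------------------------------------------------------------------------


@dataclass
class DaySeries:
    tables: dict                 # day -> cell-feature table (primary noise)
    replicate_tables: dict       # day -> independent-noise replicate
    truths: dict                 # day -> GroundTruth

    def stacked(self, replicate: bool = False) -> pd.DataFrame:
        src = self.replicate_tables if replicate else self.tables
        return pd.concat(src.values(), ignore_index=True)


def generate_day_series(config: ColonyPhantomConfig,
                        with_replicate: bool = True) -> DaySeries:
    """Table-mode day series (days from config) plus an independent-noise
    replicate for validation splits; expected abundances are shared."""
    tables, reps, truths = {}, {}, {}
    for day in config.days:
        table, truth = generate_cell_table(config, day, replicate=0)
        tables[day] = table
        truths[day] = truth
        if with_replicate:
            reps[day], _ = generate_cell_table(config, day, replicate=1)
    return DaySeries(tables=tables, replicate_tables=reps, truths=truths)


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_colony(config: ColonyPhantomConfig, day: int, outdir: str | Path,
                  replicate: int = 0) -> dict:
    """Write one day's phantom to disk: imzML+ibd, 4-channel TIFF, ground
    truth CSV/JSON.  File contents are deterministic (pinned imzML UUID)."""
    import tifffile
    from .msi import write_imzml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    confocal, dataset, truth = generate_colony(config, day, replicate)
    stem = f"day{day}" + (f"_rep{replicate}" if replicate else "")
    tiff_path = outdir / f"{stem}_confocal.tiff"
    tifffile.imwrite(tiff_path, confocal, photometric="minisblack", metadata={
        "axes": "CYX", "channels": ["Hoechst", "TRA181", "SSEA1", "NCAM1"],
        "pixel_size_um": config.confocal_pitch})
    imzml_path = outdir / f"{stem}.imzML"
    write_imzml(dataset, imzml_path, uid=(config.seed * 1000 + day * 10 + replicate))
    truth.cells.join(truth.expected).to_csv(outdir / f"{stem}_truth.csv",
                                            index=False)
    truth.transform.to_json(outdir / f"{stem}_transform.json")
    return {"confocal": tiff_path, "imzml": imzml_path,
            "truth": outdir / f"{stem}_truth.csv",
            "transform": outdir / f"{stem}_transform.json"}
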