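"""Confocal-to-MSI registration by mutual-information maximization.

The Hoechst confocal reference is blurred and resampled to the MSI pixel
pitch, then rotated, shifted, and scaled over a bounded parameter box until
the mutual information (MI) of its joint intensity histogram with the mean
ion image is maximal.  The search is coarse-to-fine: a global grid on
downsampled images, cyclic per-parameter scans at full resolution, and a
final simplex polish.  A permutation floor (MI of pixel-shuffled overlaps)
guards against accepting an alignment no better than chance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.transform import rescale

from .transform import AffineTransform2D

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# mutual information
# ---------------------------------------------------------------------------


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def mutual_information(img_a: np.ndarray, img_b: np.ndarray, n_bins: int = 32) -> float:
    """MI (bits) of the joint intensity histogram of two equal-shape images.

    Intensities are min-max scaled per image before binning; NaN pixels in
    either image are excluded (used to drop out-of-overlap pixels after
    warping).  A constant image carries no information: MI = 0, with a
    warning.
    """
    a = np.asarray(img_a, float).ravel()
    b = np.asarray(img_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    valid = np.isfinite(a) & np.isfinite(b)
    a, b = a[valid], b[valid]
    if a.size == 0:
        return 0.0
    # ptp at float-rounding scale is not structure: min-max scaling would
    # amplify numerical noise into fake entropy
    tol_a = 1e-12 * max(1.0, float(np.max(np.abs(a))))
    tol_b = 1e-12 * max(1.0, float(np.max(np.abs(b))))
    if np.ptp(a) <= tol_a or np.ptp(b) <= tol_b:
        warnings.warn("constant image: mutual information is 0")
        return 0.0
    a = (a - a.min()) / np.ptp(a)
    b = (b - b.min()) / np.ptp(b)
    joint, _, _ = np.histogram2d(a, b, bins=n_bins, range=[[0, 1], [0, 1]])
    pj = joint / joint.sum()
    pa = pj.sum(axis=1)
    pb = pj.sum(axis=0)
    return _entropy_bits(pa) + _entropy_bits(pb) - _entropy_bits(pj.ravel())


def image_entropy(img: np.ndarray, n_bins: int = 32) -> float:
    """Marginal intensity entropy H (bits) under the same binning as MI."""
    a = np.asarray(img, float).ravel()
    a = a[np.isfinite(a)]
    if a.size == 0 or np.ptp(a) == 0:
        return 0.0
    a = (a - a.min()) / np.ptp(a)
    hist, _ = np.histogram(a, bins=n_bins, range=(0, 1))
    return _entropy_bits(hist / hist.sum())


# ---------------------------------------------------------------------------
# parameter box / result containers
# ---------------------------------------------------------------------------


@dataclass
class SearchRanges:
    """Half-ranges of the registration search box (centered on identity)."""

    rotation_deg: float = 15.0
    shift_px: float = 50.0       # MSI pixels, each axis
    scale: float = 0.10          # fractional, i.e. scale in [1 - s, 1 + s]


@dataclass
class RegistrationResult:
    transform: AffineTransform2D
    mi: float
    search_trace: list = field(default_factory=list)  # [(params, mi), ...]
    converged: bool = True
    permutation_floor: float = 0.0


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------


def _warp(conf: np.ndarray, out_shape: tuple[int, int], rot_deg: float,
          dx: float, dy: float, scale: float,
          center_conf: tuple[float, float], center_out: tuple[float, float]) -> np.ndarray:
    """Sample ``conf`` on the output grid under p_out = C_o + R*s*(p - C_c) + t.

    Coordinates are (x, y); scipy's affine_transform works in (row, col), so
    axes are swapped in the matrix.  Out-of-overlap pixels become NaN.
    """
    th = np.deg2rad(rot_deg)
    c, s = np.cos(th), np.sin(th)
    inv = np.array([[c, s], [-s, c]]) / scale  # R^T / s, xy order
    # (row, col) convention: swap both input and output axes
    inv_rc = inv[::-1, ::-1]
    t = np.array([dx, dy])
    co = np.array(center_out)
    cc = np.array(center_conf)
    offset_xy = cc - inv @ (co + t)
    offset_rc = offset_xy[::-1]
    return ndimage.affine_transform(
        conf, inv_rc, offset=offset_rc, output_shape=out_shape,
        order=1, mode="constant", cval=np.nan,
    )


def _sym_grid(half: float, step: float) -> np.ndarray:
    """0, +-step, +-2*step, ... out to +-half (identity always included)."""
    k = int(np.floor(half / step + 1e-9))
    vals = np.arange(-k, k + 1) * step
    return vals[np.argsort(np.abs(vals), kind="stable")]


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def prepare_confocal_reference(conf_ref: np.ndarray, conf_pitch: float,
                               msi_pitch: float) -> np.ndarray:
    """Anti-alias blur (sigma = half the MSI pitch) and resample the confocal
    reference to the MSI pixel pitch."""
    conf = np.asarray(conf_ref, float)
    factor = conf_pitch / msi_pitch
    if abs(factor - 1.0) < 1e-9:
        return conf.copy()
    sigma_px = (msi_pitch / 2.0) / conf_pitch
    blurred = ndimage.gaussian_filter(conf, sigma_px)
    return rescale(blurred, factor, order=1, anti_aliasing=False,
                   preserve_range=True).astype(float)


def register(conf_ref: np.ndarray, msi_ref: np.ndarray, conf_pitch: float,
             msi_pitch: float, ranges: SearchRanges | None = None,
             n_bins: int = 32, seed: int = 0,
             coarse_downsample: int = 4, supersample: int = 1,
             min_overlap: float = 0.3,
             polish: bool = True) -> RegistrationResult:
    """Find the rotation/shift/scale maximizing MI between the confocal
    reference (any pitch) and the MSI reference image.

    Deterministic given the ranges and grid steps: grid ties are broken by
    the smallest parameter norm from identity.  ``converged`` is False when
    the best MI does not exceed the permutation floor (max MI over 20
    pixel-shuffled overlaps).  ``supersample`` scores the fine search levels
    on a bilinearly upsampled grid (msi_pitch / supersample); useful for
    small MSI grids where the joint-histogram sampling noise otherwise
    rivals the MI differences being compared.
    """
    ranges = ranges or SearchRanges()
    msi = np.asarray(msi_ref, float)
    conf_ds = prepare_confocal_reference(conf_ref, conf_pitch, msi_pitch)
    center_conf = ((conf_ds.shape[1] - 1) / 2.0, (conf_ds.shape[0] - 1) / 2.0)
    center_msi = ((msi.shape[1] - 1) / 2.0, (msi.shape[0] - 1) / 2.0)
    trace: list = []

    id_overlap: dict[int, int] = {}

    def score(params: np.ndarray, conf_img: np.ndarray, msi_img: np.ndarray,
              pxscale: float, cc, cm, bins: int) -> float:
        # pxscale converts shifts from original-MSI-pixel units to the grid
        # of msi_img (e.g. 1/ds at the coarse level, supersample at the fine)
        rot, dx, dy, sc = params
        warped = _warp(conf_img, msi_img.shape, rot, dx * pxscale,
                       dy * pxscale, sc, cc, cm)
        # MI estimated on a sliver of overlap is inflated (sampling bias);
        # candidates retaining < min_overlap of the identity overlap are out
        key = id(msi_img)
        if key not in id_overlap:
            ident = _warp(conf_img, msi_img.shape, 0.0, 0.0, 0.0, 1.0, cc, cm)
            id_overlap[key] = max(1, int(np.isfinite(ident).sum()))
        if np.isfinite(warped).sum() < min_overlap * id_overlap[key]:
            return -np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mutual_information(warped, msi_img, n_bins=bins)

    def _adaptive_bins(n_px: int) -> int:
        # keep the joint histogram populated (~>= 4 samples per occupied bin)
        return int(np.clip(np.sqrt(n_px / 4.0), 4, n_bins))

    def norm(p) -> float:
        rot, dx, dy, sc = p
        return (rot / max(ranges.rotation_deg, 1e-9)) ** 2 \
            + (dx ** 2 + dy ** 2) / max(ranges.shift_px, 1e-9) ** 2 \
            + ((sc - 1.0) / max(ranges.scale, 1e-9)) ** 2

    best = np.array([0.0, 0.0, 0.0, 1.0])
    # --- level 0: coarse 4-D grid on downsampled images -------------------
    ds = max(1, int(coarse_downsample))
    while ds > 1 and min(conf_ds.shape) / ds < 20:
        ds //= 2  # keep enough coarse pixels for the histogram to mean anything
    if ds > 1:
        conf_c = rescale(conf_ds, 1.0 / ds, order=1, anti_aliasing=True,
                         preserve_range=True).astype(float)
        msi_c = rescale(msi, 1.0 / ds, order=1, anti_aliasing=True,
                        preserve_range=True).astype(float)
    else:
        conf_c, msi_c = conf_ds, msi
    cc_c = ((conf_c.shape[1] - 1) / 2.0, (conf_c.shape[0] - 1) / 2.0)
    cm_c = ((msi_c.shape[1] - 1) / 2.0, (msi_c.shape[0] - 1) / 2.0)
    rot_step0, shift_step0, scale_step0 = 3.0, 2.0 * ds, 0.04
    bins_c = _adaptive_bins(conf_c.size)
    best_mi, best_norm = -np.inf, np.inf
    for rot in _sym_grid(ranges.rotation_deg, rot_step0):
        for sc in 1.0 + _sym_grid(ranges.scale, scale_step0):
            for dx in _sym_grid(ranges.shift_px, shift_step0):
                for dy in _sym_grid(ranges.shift_px, shift_step0):
                    p = np.array([rot, dx, dy, sc])
                    mi = score(p, conf_c, msi_c, 1.0 / ds, cc_c, cm_c, bins_c)
                    if mi > best_mi + 1e-12 or (
                        abs(mi - best_mi) <= 1e-12 and norm(p) < best_norm
                    ):
                        best_mi, best_norm, best = mi, norm(p), p
    trace.append((best.tolist(), best_mi))

    # fine-level scoring grid (optionally supersampled)
    ss = max(1, int(supersample))
    if ss > 1:
        conf_f = prepare_confocal_reference(conf_ref, conf_pitch, msi_pitch / ss)
        msi_f = rescale(msi, float(ss), order=1, preserve_range=True).astype(float)
    else:
        conf_f, msi_f = conf_ds, msi
    cc_f = ((conf_f.shape[1] - 1) / 2.0, (conf_f.shape[0] - 1) / 2.0)
    cm_f = ((msi_f.shape[1] - 1) / 2.0, (msi_f.shape[0] - 1) / 2.0)
    bins_f = _adaptive_bins(conf_f.size)

    # --- levels 1-2: cyclic per-parameter scans at fine resolution --------
    def scan_levels(best: np.ndarray) -> tuple[np.ndarray, float]:
        best_mi = score(best, conf_f, msi_f, float(ss), cc_f, cm_f, bins_f)
        levels = [
            (1.0, 1.0, 0.01, (rot_step0, shift_step0, scale_step0)),
            (0.25, 0.25, 0.0025, (1.5, 1.5, 0.015)),
        ]
        for rot_step, shift_step, scale_step, (rot_half, shift_half, scale_half) in levels:
            for _cycle in range(2):
                for axis, step, half in (
                    (0, rot_step, rot_half),
                    (1, shift_step, shift_half),
                    (2, shift_step, shift_half),
                    (3, scale_step, scale_half),
                ):
                    lo_lim, hi_lim = _axis_limits(axis, ranges)
                    center_val = best[axis]
                    offsets = _sym_grid(half, step)
                    for off in offsets:
                        val = center_val + off
                        if not (lo_lim - 1e-9 <= val <= hi_lim + 1e-9):
                            continue
                        p = best.copy()
                        p[axis] = val
                        mi = score(p, conf_f, msi_f, float(ss), cc_f, cm_f, bins_f)
                        if mi > best_mi + 1e-12:
                            best_mi, best = mi, p
            trace.append((best.tolist(), best_mi))
        return best, best_mi

    def _axis_limits(axis: int, r: SearchRanges) -> tuple[float, float]:
        if axis == 0:
            return -r.rotation_deg, r.rotation_deg
        if axis in (1, 2):
            return -r.shift_px, r.shift_px
        return 1.0 - r.scale, 1.0 + r.scale

    best, best_mi = scan_levels(best)

    # --- final simplex polish ---------------------------------------------
    if polish:
        def neg(p):
            q = np.array([
                np.clip(p[0], -ranges.rotation_deg, ranges.rotation_deg),
                np.clip(p[1], -ranges.shift_px, ranges.shift_px),
                np.clip(p[2], -ranges.shift_px, ranges.shift_px),
                np.clip(p[3], 1.0 - ranges.scale, 1.0 + ranges.scale),
            ])
            return -score(q, conf_f, msi_f, float(ss), cc_f, cm_f, bins_f)

        res = optimize.minimize(
            neg, best, method="Nelder-Mead",
            options={"maxiter": 150, "xatol": 1e-3, "fatol": 1e-6,
                     "initial_simplex": best + np.vstack(
                         [np.zeros(4), np.diag([0.2, 0.3, 0.3, 0.002])])},
        )
        if -res.fun > best_mi:
            best_mi = -res.fun
            best = np.array([
                np.clip(res.x[0], -ranges.rotation_deg, ranges.rotation_deg),
                np.clip(res.x[1], -ranges.shift_px, ranges.shift_px),
                np.clip(res.x[2], -ranges.shift_px, ranges.shift_px),
                np.clip(res.x[3], 1.0 - ranges.scale, 1.0 + ranges.scale),
            ])
        trace.append((best.tolist(), best_mi))

    # --- permutation floor -------------------------------------------------
    rng = np.random.default_rng(seed)
    warped_id = _warp(conf_f, msi_f.shape, 0.0, 0.0, 0.0, 1.0, cc_f, cm_f)
    valid = np.isfinite(warped_id)
    vals_a = warped_id[valid]
    vals_b = msi_f[valid]
    floor = 0.0
    for _ in range(20):
        perm = rng.permutation(len(vals_a))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            floor = max(floor, mutual_information(vals_a[perm], vals_b, n_bins=bins_f))
    converged = bool(best_mi > floor)
    if not converged:
        log.warning("registration failed: best MI %.4f <= permutation floor %.4f",
                    best_mi, floor)

    rot, dx, dy, sc = best
    transform = AffineTransform2D(
        rotation_deg=float(rot),
        dx_um=float(dx * msi_pitch),
        dy_um=float(dy * msi_pitch),
        scale=float(sc),
        msi_pitch=msi_pitch,
        center_conf_um=(center_conf[0] * msi_pitch, center_conf[1] * msi_pitch),
        center_msi_px=center_msi,
    )
    return RegistrationResult(transform=transform, mi=float(best_mi),
                              search_trace=trace, converged=converged,
                              permutation_floor=float(floor))


# ---------------------------------------------------------------------------
# contour mapping
# ---------------------------------------------------------------------------


def map_contours(contours_um: list[np.ndarray], transform: AffineTransform2D,
                 msi_shape: tuple[int, int] | None = None
                 ) -> tuple[list[np.ndarray], np.ndarray]:
    """Map confocal-frame contours (n, 2 arrays of (x, y) um) into MSI pixel
    coordinates, preserving sub-pixel positions.

    Returns the mapped contours plus a boolean "inside" flag per contour; a
    contour whose every vertex falls outside the MSI grid is flagged False
    (downstream extraction drops it) and the count is logged.
    """
    mapped = [transform.apply(c) for c in contours_um]
    if msi_shape is None:
        return mapped, np.ones(len(mapped), dtype=bool)
    h, w = msi_shape
    inside = np.array([
        bool(np.any((c[:, 0] > -0.5) & (c[:, 0] < w - 0.5)
                    & (c[:, 1] > -0.5) & (c[:, 1] < h - 0.5)))
        for c in mapped
    ])
    n_out = int((~inside).sum())
    if n_out:
        log.info("map_contours: %d contour(s) fully outside the MSI grid", n_out)
    return mapped, inside


def contours_to_geojson(contours: list[np.ndarray], frame: str) -> dict:
    """Contours as a GeoJSON-style FeatureCollection (one Polygon per
    nucleus); ``frame`` records the coordinate frame ("confocal_um" or
    "msi_px")."""
    features = []
    for i, c in enumerate(contours):
        ring = np.vstack([c, c[:1]])  # closed ring
        features.append({
            "type": "Feature",
            "properties": {"id": i, "frame": frame},
            "geometry": {"type": "Polygon",
                         "coordinates": [ring.tolist()]},
        })
    return {"type": "FeatureCollection", "features": features}
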