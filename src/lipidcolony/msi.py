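"""Mass-spectrometry-imaging core: datasets, baseline removal, peak binning, ion images.

An MSI dataset is a rectangular pixel grid in which every pixel carries a
mass spectrum (centroided ``(m/z, intensity)`` pairs for TOF/FTICR exports,
or profile traces that still need centroiding).  This module ingests
imzML+ibd pairs, estimates and removes slowly-varying baselines from profile
spectra, pools centroid peaks across pixels into disjoint m/z feature
intervals (single-linkage merging at a configurable minimum interval width,
20 mDa by default, to absorb run-long peak drift), renders per-feature ion
images, and screens features for association with the colony footprint.
"""

from __future__ import annotations

import contextlib
import logging
import uuid as _uuid
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_MIN_INTERVAL = 0.020  # Th; full interval width floor for peak merging


class FormatError(ValueError):
    """Raised for missing/corrupt imzML+ibd input."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class MSIDataset:
    """Pixel grid of mass spectra with spatial calibration.

    ``spectra[i]`` is a ``(mz, intensity)`` pair of 1-D float arrays for the
    pixel at ``coords[i] = (row, col)`` (0-based, pixel centers).  Missing
    grid positions are allowed; ``shape`` is the bounding grid.
    """

    spectra: list[tuple[np.ndarray, np.ndarray]]
    coords: np.ndarray  # (n, 2) int, (row, col)
    shape: tuple[int, int]
    pixel_size: float  # um/px
    mz_range: tuple[float, float] = (200.0, 1600.0)
    mode: str = "centroid"  # "centroid" | "profile"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.mode not in ("centroid", "profile"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self._index = {tuple(rc): i for i, rc in enumerate(map(tuple, self.coords))}
        for mz, inten in self.spectra:
            if len(mz) and np.any(np.diff(mz) <= 0):
                raise FormatError("m/z values must be strictly increasing within a spectrum")
            if len(inten) and np.any(np.asarray(inten) < 0):
                raise ValueError("intensities must be >= 0")

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)

    def spectrum(self, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
        return self.spectra[self._index[(row, col)]]

    def pooled_centroids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All centroids across pixels: (mz, intensity, pixel_index)."""
        mzs, intens, idx = [], [], []
        for i, (mz, inten) in enumerate(self.spectra):
            mzs.append(np.asarray(mz, float))
            intens.append(np.asarray(inten, float))
            idx.append(np.full(len(mz), i))
        if not mzs:
            return np.array([]), np.array([]), np.array([], dtype=int)
        return np.concatenate(mzs), np.concatenate(intens), np.concatenate(idx).astype(int)


@dataclass(frozen=True)
class PeakFeature:
    """A disjoint m/z interval with its mean peak center and optional lipid name."""

    center_mz: float
    interval: tuple[float, float]
    label: str = ""
    annotation: str | None = None

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not (lo <= self.center_mz <= hi):
            raise ValueError("interval must contain center_mz")
        if hi - lo < DEFAULT_MIN_INTERVAL - 1e-12:
            raise ValueError("interval narrower than the minimum width")
        if not self.label:
            object.__setattr__(self, "label", f"{self.center_mz:.1f}")


@dataclass
class FeatureSet:
    """Ordered, disjoint peak features (sorted by center m/z)."""

    features: list[PeakFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: f.center_mz)
        for a, b in zip(self.features, self.features[1:]):
            if a.interval[1] > b.interval[0] + 1e-12:
                raise ValueError(
                    f"feature intervals overlap: {a.interval} vs {b.interval}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.features]

    @property
    def centers(self) -> np.ndarray:
        return np.array([f.center_mz for f in self.features])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "label": [f.label for f in self.features],
                "center_mz": [f.center_mz for f in self.features],
                "interval_lo": [f.interval[0] for f in self.features],
                "interval_hi": [f.interval[1] for f in self.features],
                "annotation": [f.annotation or "" for f in self.features],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureSet":
        df = pd.read_csv(path, keep_default_na=False)
        return cls(
            [
                PeakFeature(
                    center_mz=float(r.center_mz),
                    interval=(float(r.interval_lo), float(r.interval_hi)),
                    label=str(r.label),
                    annotation=str(r.annotation) or None,
                )
                for r in df.itertuples()
            ]
        )


@dataclass
class IonImage:
    """Per-pixel intensity inside one feature interval (or the full-spectrum mean)."""

    values: np.ndarray
    feature: PeakFeature | str
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("ion image values must be >= 0")

    def to_tiff(self, path: str | Path) -> None:
        import tifffile

        tifffile.imwrite(
            str(path),
            self.values.astype(np.float32),
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={"unit": "um", "pixel_size_um": self.pixel_size},
        )


# ---------------------------------------------------------------------------
# imzML I/O (pyimzml-backed)
# ---------------------------------------------------------------------------


def read_imzml(path: str | Path, pixel_size: float | None = None,
               mz_range: tuple[float, float] = (200.0, 1600.0)) -> MSIDataset:
    """Read an imzML+ibd pair into an :class:`MSIDataset`.

    imzML coordinates are 1-based (x, y); they are converted to 0-based
    (row, col).  ``pixel_size`` falls back to the file's "pixel size x"
    scan-settings entry, else 10 um with a warning (the TOF raster pitch).
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not path.exists():
        raise FormatError(f"missing imzML file: {path}")
    if not ibd.exists():
        raise FormatError(f"missing ibd file for {path}")
    parser = ImzMLParser(str(path))
    if pixel_size is None:
        px = parser.imzmldict.get("pixel size x")
        if px:
            pixel_size = float(px)
        else:
            warnings.warn("pixel size not recorded in imzML; assuming 10 um/px")
            pixel_size = 10.0

    profile = "profile spectrum" in getattr(parser, "metadata", None).file_description.param_by_name \
        if getattr(parser, "metadata", None) else False
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    coords = []
    for i, (x, y, *_z) in enumerate(parser.coordinates):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        if len(mz) and np.any(np.diff(mz) <= 0):
            raise FormatError(f"non-monotone m/z array in spectrum {i}")
        spectra.append((mz, inten))
        coords.append((int(y) - 1, int(x) - 1))
    coords = np.asarray(coords, dtype=int).reshape(-1, 2)
    if len(coords):
        shape = (int(coords[:, 0].max()) + 1, int(coords[:, 1].max()) + 1)
    else:
        shape = (0, 0)
    lo = min((float(mz[0]) for mz, _ in spectra if len(mz)), default=mz_range[0])
    hi = max((float(mz[-1]) for mz, _ in spectra if len(mz)), default=mz_range[1])
    return MSIDataset(
        spectra=spectra,
        coords=coords,
        shape=shape,
        pixel_size=pixel_size,
        mz_range=(min(lo, mz_range[0]), max(hi, mz_range[1])),
        mode="profile" if profile else "centroid",
    )


@contextlib.contextmanager
def _fixed_writer_uuid(uid: _uuid.UUID | None):
    """Pin the UUID pyimzml stamps into the imzML/ibd pair (for reproducible exports)."""
    import pyimzml.ImzMLWriter as _W

    if uid is None:
        yield
        return

    class _Shim:
        @staticmethod
        def uuid4():
            return uid

    original = _W.uuid
    _W.uuid = _Shim
    try:
        yield
    finally:
        _W.uuid = original


def write_imzml(dataset: MSIDataset, path: str | Path,
                uid: _uuid.UUID | int | None = None) -> None:
    """Write a centroid-mode dataset as a processed-mode imzML+ibd pair.

    Passing ``uid`` pins the file UUID so repeated exports are byte-identical.
    m/z and intensity are stored as float64, so read-back is bit-exact.
    """
    from pyimzml.ImzMLWriter import ImzMLWriter

    import pyimzml.ImzMLWriter as _W

    class _Writer(ImzMLWriter):
        # pyimzml chokes on zero-length spectra (np.min of empty); register
        # them explicitly so empty pixels survive a write->read round trip
        def addSpectrum(self, mzs, intensities, coords, userParams=[]):
            if len(mzs) > 0:
                return super().addSpectrum(mzs, intensities, coords, userParams)
            mz_off, mz_len, mz_enc = self._encode_and_write(
                np.array([], dtype=float), self.mz_dtype, self.mz_compression)
            int_off, int_len, int_enc = self._encode_and_write(
                np.array([], dtype=float), self.intensity_dtype,
                self.intensity_compression)
            self.spectra.append(_W._Spectrum(
                coords, mz_len, mz_off, mz_enc, int_len, int_off, int_enc,
                0.0, 0.0, 0.0, 0.0, 0.0, userParams))

    if isinstance(uid, int):
        uid = _uuid.UUID(int=uid & ((1 << 128) - 1))
    with _fixed_writer_uuid(uid):
        writer = _Writer(
            str(Path(path).with_suffix("")),
            mz_dtype=np.float64,
            intensity_dtype=np.float64,
            mode="processed",
            spec_type="centroid",
            polarity="negative",
        )
    with writer as w:
        for (row, col), (mz, inten) in zip(dataset.coords, dataset.spectra):
            w.addSpectrum(np.asarray(mz, float), np.asarray(inten, float),
                          (int(col) + 1, int(row) + 1, 1))


# ---------------------------------------------------------------------------
# baseline removal
# ---------------------------------------------------------------------------


def remove_baseline(mz: np.ndarray, intensity: np.ndarray, window: float = 1.0,
                    max_iter: int = 20, tol: float = 1e-9,
                    mode: str = "profile") -> np.ndarray:
    """Subtract an iteratively-smoothed lower envelope from a profile spectrum.

    The baseline starts at the raw trace and is driven down by repeating
    ``b <- min(b, smooth(b, window))`` with a moving-average kernel of width
    ``window`` (Th) until it stops changing or ``max_iter`` passes; what
    survives the subtraction is clipped at zero.  Broad pedestals collapse
    into the baseline while peaks much narrower than ``window`` are spared.
    """
    if mode != "profile":
        raise ValueError("baseline removal applies to profile-mode spectra only")
    if window <= 0:
        raise ValueError("window must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if len(mz) < 2:
        return np.zeros_like(intensity)
    spacing = float(np.median(np.diff(mz)))
    half = max(1, int(round(window / spacing / 2)))
    kernel = np.ones(2 * half + 1)
    kernel /= kernel.sum()

    def smooth(v: np.ndarray) -> np.ndarray:
        padded = np.pad(v, half, mode="edge")
        return np.convolve(padded, kernel, mode="valid")

    baseline = intensity.copy()
    for _ in range(max_iter):
        candidate = np.minimum(baseline, smooth(baseline))
        if np.max(np.abs(candidate - baseline)) < tol:
            baseline = candidate
            break
        baseline = candidate
    return np.clip(intensity - baseline, 0.0, None)


# ---------------------------------------------------------------------------
# peak picking / binning
# ---------------------------------------------------------------------------


def _single_linkage_1d(centers: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Partition sorted 1-D points into single-linkage clusters: split where
    the gap between consecutive points is >= threshold."""
    order = np.argsort(centers, kind="stable")
    sorted_c = centers[order]
    if len(sorted_c) == 0:
        return []
    breaks = np.nonzero(np.diff(sorted_c) >= threshold)[0]
    groups = np.split(order, breaks + 1)
    return groups


def pick_and_bin_peaks(dataset: MSIDataset, min_interval: float = DEFAULT_MIN_INTERVAL,
                       min_pixel_fraction: float = 0.01) -> FeatureSet:
    """Pool centroid peaks across pixels and merge them into disjoint features.

    Peak centers closer than ``min_interval`` (single-linkage, i.e. chains of
    sub-threshold gaps merge) become one feature whose center is the mean of
    its members and whose interval is ``center +- max(min_interval/2, observed
    spread)``; adjacent intervals are clipped at the midpoint between cluster
    edges so the set stays disjoint.  Features seen in fewer than
    ``min_pixel_fraction`` of pixels are dropped.
    """
    if dataset.mode != "centroid":
        raise ValueError("dataset must be centroided before peak binning")
    mz, _inten, pix = dataset.pooled_centroids()
    if len(mz) == 0:
        warnings.warn("empty dataset: no centroids to bin")
        return FeatureSet([])
    groups = _single_linkage_1d(mz, min_interval)
    n_pixels = max(dataset.n_pixels, 1)
    raw: list[tuple[float, float, float]] = []  # (center, lo, hi)
    for g in groups:
        members = mz[g]
        if len(np.unique(pix[g])) / n_pixels < min_pixel_fraction:
            continue
        center = float(members.mean())
        spread = float(np.max(np.abs(members - center))) if len(members) > 1 else 0.0
        half = max(min_interval / 2, spread)
        raw.append((center, center - half, center + half))
    # adjacent cluster centers are >= min_interval apart (single linkage), so
    # cutting any overlapping pair at the midpoint between centers preserves
    # at least the minimum half-width on both sides
    raw.sort(key=lambda t: t[0])
    bounds = [[lo, hi] for _, lo, hi in raw]
    for i in range(len(raw) - 1):
        if bounds[i][1] > bounds[i + 1][0]:
            mid = (raw[i][0] + raw[i + 1][0]) / 2
            bounds[i][1] = min(bounds[i][1], mid)
            bounds[i + 1][0] = max(bounds[i + 1][0], mid)
    feats = [
        PeakFeature(center_mz=center, interval=(lo, hi))
        for (center, _, _), (lo, hi) in zip(raw, bounds)
    ]
    return FeatureSet(feats)


# ---------------------------------------------------------------------------
# ion images
# ---------------------------------------------------------------------------


def build_ion_image(dataset: MSIDataset, feature: PeakFeature,
                    statistic: str = "sum") -> IonImage:
    """Render one feature's spatial map: per pixel, the sum (default) or mean
    of centroid intensities whose m/z falls inside the feature interval."""
    lo, hi = feature.interval
    values = np.zeros(dataset.shape, dtype=float)
    for (row, col), (mz, inten) in zip(dataset.coords, dataset.spectra):
        if len(mz) == 0:
            continue
        mask = (mz >= lo) & (mz <= hi)
        if not mask.any():
            continue
        if statistic == "sum":
            values[row, col] = float(np.sum(inten[mask]))
        elif statistic == "mean":
            values[row, col] = float(np.mean(inten[mask]))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    return IonImage(values=values, feature=feature, pixel_size=dataset.pixel_size)


def build_ion_images(dataset: MSIDataset, featureset: FeatureSet,
                     statistic: str = "sum") -> dict[str, IonImage]:
    """Vectorized multi-feature rendering (one pass over the spectra)."""
    edges_lo = np.array([f.interval[0] for f in featureset])
    edges_hi = np.array([f.interval[1] for f in featureset])
    stacks = np.zeros((len(featureset),) + dataset.shape, dtype=float)
    counts = np.zeros_like(stacks)
    for (row, col), (mz, inten) in zip(dataset.coords, dataset.spectra):
        if len(mz) == 0:
            continue
        lo_idx = np.searchsorted(edges_lo, mz, side="right") - 1
        valid = (lo_idx >= 0) & (mz <= edges_hi[np.clip(lo_idx, 0, None)])
        if not valid.any():
            continue
        np.add.at(stacks, (lo_idx[valid], row, col), inten[valid])
        np.add.at(counts, (lo_idx[valid], row, col), 1.0)
    if statistic == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            stacks = np.where(counts > 0, stacks / counts, 0.0)
    elif statistic != "sum":
        raise ValueError(f"unknown statistic {statistic!r}")
    return {
        f.label: IonImage(values=stacks[i], feature=f, pixel_size=dataset.pixel_size)
        for i, f in enumerate(featureset)
    }


def mean_ion_image(dataset: MSIDataset) -> IonImage:
    """Per-pixel mean over all centroid intensities — the MSI-side
    registration reference (empty-spectrum pixels are 0)."""
    values = np.zeros(dataset.shape, dtype=float)
    for (row, col), (mz, inten) in zip(dataset.coords, dataset.spectra):
        values[row, col] = float(np.mean(inten)) if len(inten) else 0.0
    return IonImage(values=values, feature="mean-over-spectrum",
                    pixel_size=dataset.pixel_size)


def tic_normalize(dataset: MSIDataset) -> MSIDataset:
    """Optional per-pixel total-ion-current normalization (off by default in
    every pipeline stage); each spectrum is scaled so its intensity sum is 1."""
    spectra = []
    for mz, inten in dataset.spectra:
        total = float(np.sum(inten))
        spectra.append((mz.copy(), inten / total if total > 0 else inten.copy()))
    out = replace(dataset, spectra=spectra)
    return out


# ---------------------------------------------------------------------------
# feature screening
# ---------------------------------------------------------------------------


def point_biserial(values: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation between a real image and a boolean mask."""
    v = np.asarray(values, float).ravel()
    m = np.asarray(mask, bool).ravel().astype(float)
    if m.all() or not m.any():
        raise ValueError("mask must contain both True and False pixels")
    if np.std(v) == 0:
        return 0.0
    return float(np.corrcoef(v, m)[0, 1])


def screen_features(featureset: FeatureSet, ion_images: dict[str, IonImage],
                    colony_mask: np.ndarray, threshold: float = 0.3) -> FeatureSet:
    """Keep features whose ion image is positively associated with the colony
    footprint (point-biserial correlation above ``threshold``).  Automates the
    manual screening step of selecting colony-distributed m/z features."""
    colony_mask = np.asarray(colony_mask, bool)
    if colony_mask.all() or not colony_mask.any():
        raise ValueError("colony mask is degenerate (all-true or all-false)")
    kept = []
    for f in featureset:
        img = ion_images[f.label]
        if img.values.shape != colony_mask.shape:
            raise ValueError("ion image and mask shapes differ")
        r = point_biserial(img.values, colony_mask)
        if r > threshold:
            kept.append(f)
    log.info("screen_features kept %d/%d features", len(kept), len(featureset))
    return FeatureSet(kept)
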