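"""Spectral containers, file I/O and the preprocessing chain.

A Raman spectrum enters the factorization after a fixed sequence of
steps: cosmic-ray removal, baseline subtraction, clipping of negative
residuals, and normalization to unit area under the curve.  The stage
of each spectrum is tracked explicitly and transitions are enforced so
that, e.g., area normalization cannot silently run on a raw spectrum
that still carries its fluorescence background.

Containers
----------
``WavenumberAxis``
    Strictly increasing grid of Raman shifts (cm^-1).
``RamanSpectrum``
    One spectrum with its axis and processing stage.
``SpectralDataset``
    Matrix of spectra (rows) on a shared axis plus per-row metadata
    (cell line, dose in Gy, day post-irradiation, replicate, cell id).
``BasisLibrary``
    Named reference spectra of pure biochemicals, processed with the
    identical normalization as the cell spectra so that scores are
    comparable across factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded
from scipy.ndimage import median_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    AxisError,
    AxisMismatchError,
    CoverageError,
    DegenerateSpectrumError,
    DuplicateNameError,
    MetadataError,
    SpectrumError,
    StageError,
)

STAGES = ("raw", "despiked", "baselined", "normalized")

METADATA_COLUMNS = ("cell_line", "dose_gy", "day", "replicate", "cell_id")

DEFAULT_AXIS_MIN = 450.0
DEFAULT_AXIS_MAX = 1800.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise AxisError("axis must be a 1-d array of length >= 2")
        if not np.all(np.isfinite(values)):
            raise AxisError("axis contains non-finite values")
        if not np.all(np.diff(values) > 0):
            raise AxisError("axis must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


def default_axis(start: float = DEFAULT_AXIS_MIN, stop: float = DEFAULT_AXIS_MAX,
                 step: float = 2.0) -> WavenumberAxis:
    """The instrument window used throughout: 450-1800 cm^-1."""
    return WavenumberAxis(np.arange(start, stop + 0.5 * step, step))


@dataclass(frozen=True)
class RamanSpectrum:
    """A single spectrum with its processing stage."""

    axis: WavenumberAxis
    intensities: np.ndarray
    stage: str = "raw"

    def __post_init__(self):
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", intens)
        if intens.shape != (len(self.axis),):
            raise AxisMismatchError(
                f"intensities length {intens.shape} != axis length {len(self.axis)}"
            )
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if self.stage == "normalized":
            if np.any(intens < 0):
                raise StageError("normalized spectrum has negative intensities")
            area = np.trapezoid(intens, self.axis.values)
            if abs(area - 1.0) > 1e-9:
                raise StageError(f"normalized spectrum has area {area}, not 1")

    def with_intensities(self, intensities, stage: str) -> "RamanSpectrum":
        return RamanSpectrum(self.axis, intensities, stage)


@dataclass
class SpectralDataset:
    """n spectra (rows of X) on one axis, with per-row metadata."""

    X: np.ndarray
    axis: WavenumberAxis
    meta: pd.DataFrame
    stage: str = "normalized"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.axis):
            raise AxisMismatchError(
                f"X shape {self.X.shape} incompatible with axis length {len(self.axis)}"
            )
        if len(self.meta) != self.X.shape[0]:
            raise MetadataError(
                f"metadata has {len(self.meta)} rows for {self.X.shape[0]} spectra"
            )
        missing = [c for c in METADATA_COLUMNS if c not in self.meta.columns]
        if missing:
            raise MetadataError(f"metadata missing required columns: {missing}")
        if not np.all(np.isfinite(self.X)):
            raise SpectrumError("dataset contains non-finite intensities")
        if self.stage == "normalized":
            areas = np.trapezoid(self.X, self.axis.values, axis=1)
            if np.any(np.abs(areas - 1.0) > 1e-9):
                bad = int(np.argmax(np.abs(areas - 1.0)))
                raise StageError(
                    f"spectrum {bad} has area {areas[bad]!r}, expected 1"
                )
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    def spectrum(self, i: int) -> RamanSpectrum:
        return RamanSpectrum(self.axis, self.X[i], self.stage)


@dataclass
class BasisLibrary:
    """Named reference spectra forming the fixed rows of the basis matrix."""

    names: list[str]
    B: np.ndarray
    axis: WavenumberAxis

    def __post_init__(self):
        self.names = list(self.names)
        self.B = np.asarray(self.B, dtype=float)
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise DuplicateNameError(f"duplicate basis names: {dupes}")
        if len(self.names) < 1:
            raise DuplicateNameError("library must contain at least one basis")
        if self.B.shape != (len(self.names), len(self.axis)):
            raise AxisMismatchError(
                f"B shape {self.B.shape} != ({len(self.names)}, {len(self.axis)})"
            )
        if np.any(self.B < 0):
            raise SpectrumError("library contains negative intensities")

    @property
    def m(self) -> int:
        return len(self.names)

    def row(self, name: str) -> np.ndarray:
        return self.B[self.names.index(name)]


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def read_spectrum_file(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavenumber, intensity) text file; '#' comments allowed."""
    arr = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    if arr.shape[1] < 2:
        raise SpectrumError(f"{path}: expected two columns", spectrum_id=str(path))
    return arr[:, 0], arr[:, 1]


def write_spectrum_file(path, wavenumbers, intensities, header: str = "") -> None:
    data = np.column_stack([wavenumbers, intensities])
    np.savetxt(path, data, fmt=_FLOAT_FMT, header=header)


def load_dataset(matrix_path, metadata_path, stage: str = "normalized") -> SpectralDataset:
    """Load a matrix CSV (header row = wavenumbers, one spectrum per row)
    plus a metadata CSV joined by row order."""
    mat = pd.read_csv(matrix_path, comment="#")
    try:
        wavenumbers = np.array([float(c) for c in mat.columns])
    except ValueError as exc:
        raise AxisError(f"matrix header is not numeric wavenumbers: {exc}") from exc
    axis = WavenumberAxis(wavenumbers)
    meta = pd.read_csv(metadata_path, comment="#")
    return SpectralDataset(mat.to_numpy(dtype=float), axis, meta, stage=stage)


def save_dataset(dataset: SpectralDataset, matrix_path, metadata_path,
                 header: str = "") -> None:
    cols = [_FLOAT_FMT % w for w in dataset.axis.values]
    frame = pd.DataFrame(dataset.X, columns=cols)
    for path, obj in ((matrix_path, frame), (metadata_path, dataset.meta)):
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            obj.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def load_library(paths: Sequence, names: Sequence[str],
                 target_axis: WavenumberAxis) -> BasisLibrary:
    """Load reference spectra, resample onto ``target_axis`` and normalize
    them identically to cell spectra (clip negatives, unit area)."""
    names = list(names)
    if len(paths) != len(names):
        raise MetadataError(f"{len(paths)} paths but {len(names)} names")
    rows = []
    for path, name in zip(paths, names):
        w, y = read_spectrum_file(path)
        order = np.argsort(w)
        spec = RamanSpectrum(WavenumberAxis(w[order]), y[order], stage="baselined")
        try:
            spec = resample_to_axis(spec, target_axis)
        except CoverageError as exc:
            raise CoverageError(f"library spectrum {name!r}: {exc}") from exc
        rows.append(normalize_area(spec).intensities)
    return BasisLibrary(names, np.array(rows), target_axis)


def load_library_manifest(manifest_path, target_axis: WavenumberAxis) -> BasisLibrary:
    """Manifest CSV with columns ``name,path`` (paths relative to the manifest)."""
    manifest = pd.read_csv(manifest_path, comment="#")
    for col in ("name", "path"):
        if col not in manifest.columns:
            raise MetadataError(f"library manifest missing column {col!r}")
    base = Path(manifest_path).parent
    paths = [base / p for p in manifest["path"]]
    return load_library(paths, list(manifest["name"]), target_axis)


def save_library(library: BasisLibrary, directory, manifest_name="library.csv") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for name, row in zip(library.names, library.B):
        fname = f"{name}.txt"
        write_spectrum_file(directory / fname, library.axis.values, row)
        records.append({"name": name, "path": fname})
    manifest = directory / manifest_name
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------


def resample_to_axis(spectrum: RamanSpectrum, target: WavenumberAxis) -> RamanSpectrum:
    """Linear interpolation onto ``target``; identity when the axes are equal."""
    if spectrum.axis == target:
        return spectrum
    lo, hi = spectrum.axis.span
    tlo, thi = target.span
    if tlo < lo or thi > hi:
        raise CoverageError(
            f"target [{tlo}, {thi}] cm^-1 not covered by source [{lo}, {hi}] cm^-1"
        )
    interp = np.interp(target.values, spectrum.axis.values, spectrum.intensities)
    return RamanSpectrum(target, interp, spectrum.stage)


def _robust_diff_scale(d: np.ndarray) -> tuple[np.ndarray, float]:
    """Modified z-scores of first differences and the underlying MAD scale.

    The MAD is floored at a small fraction of the largest difference so
    that numerically-flat regions of noiseless spectra (Gaussian tails)
    do not register as outliers.
    """
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    floor = 1e-6 * np.max(np.abs(d - med), initial=0.0)
    mad = max(mad, floor, np.finfo(float).tiny)
    z = 0.6745 * (d - med) / mad
    scale = mad / 0.6745
    return z, scale


def cosmic_ray_mask(intensities: np.ndarray, window: int = 11,
                    z_threshold: float = 8.0, max_spike_width: int = 2) -> np.ndarray:
    """Boolean mask of cosmic-ray pixels.

    Three-stage scheme built on the modified z-score of the first
    differences.  (1) Pixels adjacent to an outlying difference
    (|z| > threshold) become candidates.  (2) Candidates are grouped
    into contiguous runs; a spike of ``w`` pixels produces a run of
    ``w + 2`` candidates (one guard pixel each side), so only runs of
    at most ``max_spike_width + 2`` pixels are kept — a cosmic ray hits
    one or two CCD pixels while a genuine Raman band, however intense,
    spans many, and this is what keeps sharp real peaks out of the
    mask.  (3) A surviving run is
    confirmed when its residual against a linear interpolation through
    the nearest non-candidate pixels also exceeds the threshold on the
    same robust scale.
    """
    y = np.asarray(intensities, dtype=float)
    p = y.size
    if window > p:
        raise SpectrumError(f"despike window {window} exceeds spectrum length {p}")
    d = np.diff(y)
    z, scale = _robust_diff_scale(d)
    big = np.abs(z) > z_threshold
    candidates = np.zeros(p, dtype=bool)
    candidates[:-1] |= big
    candidates[1:] |= big
    mask = np.zeros(p, dtype=bool)
    if candidates.any():
        good_idx = np.flatnonzero(~candidates)
        if good_idx.size >= 2:
            interp = np.interp(np.arange(p), good_idx, y[good_idx])
            starts = np.flatnonzero(candidates & ~np.roll(candidates, 1))
            if candidates[0] and 0 not in starts:
                starts = np.append(0, starts)
            for start in starts:
                end = start
                while end + 1 < p and candidates[end + 1]:
                    end += 1
                if end - start + 1 <= max_spike_width + 2:
                    run = slice(start, end + 1)
                    hit = np.abs(y[run] - interp[run]) > z_threshold * scale
                    mask[run] |= hit
    # Second tier: a spike merged into a band's candidate run escapes the
    # run-length gate, but no genuine Raman feature stands above its own
    # 5-pixel median-filtered surroundings by more than the spectrum's
    # robust amplitude, while a cosmic ray (tens of times the median
    # intensity, 1-2 pixels wide) does.
    smooth = median_filter(y, size=5, mode="nearest")
    amplitude = np.quantile(smooth, 0.99) - np.quantile(smooth, 0.01)
    prominence = y - smooth
    mask |= prominence > np.maximum(amplitude, z_threshold * scale)
    return mask


def remove_cosmic_rays(spectrum: RamanSpectrum, window: int = 11,
                       z_threshold: float = 8.0,
                       max_spike_width: int = 2) -> RamanSpectrum:
    """Replace cosmic-ray pixels by interpolation from unflagged neighbours.

    Pixels off the repair mask are returned bitwise unchanged.
    """
    if spectrum.stage not in ("raw",):
        raise StageError(f"despike expects a raw spectrum, got {spectrum.stage!r}")
    y = spectrum.intensities
    mask = cosmic_ray_mask(y, window=window, z_threshold=z_threshold,
                           max_spike_width=max_spike_width)
    out = y.copy()
    if mask.any():
        good_idx = np.flatnonzero(~mask)
        if good_idx.size >= 2:
            out[mask] = np.interp(np.flatnonzero(mask), good_idx, y[good_idx])
    return spectrum.with_intensities(out, "despiked")


def asymmetric_least_squares_baseline(y: np.ndarray, smoothness: float = 1e5,
                                      asymmetry: float = 0.001,
                                      n_iter: int = 10) -> np.ndarray:
    """Estimate a smooth fluorescence baseline by asymmetric least squares.

    Whittaker smoother with a second-difference penalty: minimize
    ``sum_i w_i (y_i - z_i)^2 + lam * sum_i (z_{i-1} - 2 z_i + z_{i+1})^2``
    re-weighting with ``w_i = p`` above the baseline and ``1 - p`` below,
    so the fit hugs the lower envelope of the spectrum while Raman peaks
    (positive excursions) are ignored.  The pentadiagonal system is
    solved with a banded Cholesky-free LAPACK call per iteration.
    """
    if smoothness <= 0:
        raise ValueError(f"smoothness must be positive, got {smoothness}")
    y = np.asarray(y, dtype=float)
    p = y.size
    if p < 4:
        return np.full(p, np.median(y))
    # Banded representation of lam * D2.T @ D2 (pentadiagonal, symmetric):
    # main diagonal [1, 5, 6, ..., 6, 5, 1], first off-diagonal
    # [-2, -4, ..., -4, -2], second off-diagonal all ones.
    diag = np.full(p, 6.0)
    diag[[0, -1]] = 1.0
    diag[[1, -2]] = 5.0
    off1 = np.full(p - 1, -4.0)
    off1[[0, -1]] = -2.0
    dtd = np.zeros((5, p))
    dtd[0, 2:] = 1.0
    dtd[1, 1:] = off1
    dtd[2, :] = diag
    dtd[3, :-1] = off1
    dtd[4, :-2] = 1.0
    dtd *= smoothness
    w = np.ones(p)
    z = y
    for _ in range(n_iter):
        ab = dtd.copy()
        ab[2, :] += w
        z = solve_banded((2, 2), ab, w * y)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def subtract_baseline(spectrum: RamanSpectrum, smoothness: float = 1e5,
                      asymmetry: float = 0.001, n_iter: int = 10) -> RamanSpectrum:
    """Subtract the estimated fluorescence/substrate baseline."""
    if spectrum.stage not in ("raw", "despiked"):
        raise StageError(
            f"baseline expects a raw or despiked spectrum, got {spectrum.stage!r}"
        )
    baseline = asymmetric_least_squares_baseline(
        spectrum.intensities, smoothness=smoothness, asymmetry=asymmetry,
        n_iter=n_iter,
    )
    return spectrum.with_intensities(spectrum.intensities - baseline, "baselined")


def normalize_area(spectrum: RamanSpectrum) -> RamanSpectrum:
    """Clip negatives to zero and scale to unit area under the curve.

    Area is the trapezoidal integral over the wavenumber axis, so the
    convention is well defined on non-uniform grids.  Scale invariant and
    idempotent.
    """
    if spectrum.stage == "raw":
        raise StageError("normalize expects a baseline-subtracted spectrum")
    y = np.clip(spectrum.intensities, 0.0, None)
    area = np.trapezoid(y, spectrum.axis.values)
    if area <= 0:
        raise DegenerateSpectrumError(
            "spectrum has no positive signal; cannot normalize area"
        )
    return spectrum.with_intensities(y / area, "normalized")


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the fixed despike -> baseline -> clip -> normalize chain."""

    despike_window: int = 11
    despike_z_threshold: float = 8.0
    despike_max_width: int = 2
    baseline_smoothness: float = 1e5
    baseline_asymmetry: float = 0.001
    baseline_iterations: int = 10


def preprocess_spectrum(spectrum: RamanSpectrum,
                        config: PreprocessConfig = PreprocessConfig()) -> RamanSpectrum:
    spec = remove_cosmic_rays(
        spectrum, window=config.despike_window,
        z_threshold=config.despike_z_threshold,
        max_spike_width=config.despike_max_width,
    )
    spec = subtract_baseline(
        spec, smoothness=config.baseline_smoothness,
        asymmetry=config.baseline_asymmetry, n_iter=config.baseline_iterations,
    )
    return normalize_area(spec)


def _spectrum_ident(dataset: SpectralDataset, i: int) -> str:
    return "/".join(str(dataset.meta.iloc[i][c]) for c in METADATA_COLUMNS)


def preprocess_dataset(dataset: SpectralDataset,
                       config: PreprocessConfig = PreprocessConfig()) -> SpectralDataset:
    """Apply the full preprocessing chain to every spectrum of a raw dataset.

    The order is fixed: despike, baseline subtraction, clip, area
    normalization.  Per-spectrum failures are re-raised with the
    offending cell id attached.
    """
    if dataset.stage != "raw":
        raise StageError(f"preprocess expects a raw dataset, got {dataset.stage!r}")
    out = np.empty_like(dataset.X)
    for i in range(dataset.n_spectra):
        try:
            out[i] = preprocess_spectrum(dataset.spectrum(i), config).intensities
        except (SpectrumError, DegenerateSpectrumError, StageError) as exc:
            raise SpectrumError(
                f"preprocessing failed for spectrum {i} "
                f"({_spectrum_ident(dataset, i)}): {exc}",
                spectrum_id=_spectrum_ident(dataset, i),
            ) from exc
    return SpectralDataset(out, dataset.axis, dataset.meta.copy(),
                           stage="normalized")


class RamanPreprocessor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the preprocessing chain.

    Operates on a plain ``(n_spectra, n_wavenumbers)`` array given the
    shared wavenumber axis, so it composes with sklearn pipelines.

    Parameters
    ----------
    axis : WavenumberAxis
        Shared grid of the input rows.
    despike_window, despike_z_threshold, baseline_smoothness,
    baseline_asymmetry, baseline_iterations : see :class:`PreprocessConfig`.
    """

    def __init__(self, axis=None, despike_window=11, despike_z_threshold=8.0,
                 despike_max_width=2, baseline_smoothness=1e5,
                 baseline_asymmetry=0.001, baseline_iterations=10):
        self.axis = axis
        self.despike_window = despike_window
        self.despike_z_threshold = despike_z_threshold
        self.despike_max_width = despike_max_width
        self.baseline_smoothness = baseline_smoothness
        self.baseline_asymmetry = baseline_asymmetry
        self.baseline_iterations = baseline_iterations

    def _config(self) -> PreprocessConfig:
        return PreprocessConfig(
            despike_window=self.despike_window,
            despike_z_threshold=self.despike_z_threshold,
            despike_max_width=self.despike_max_width,
            baseline_smoothness=self.baseline_smoothness,
            baseline_asymmetry=self.baseline_asymmetry,
            baseline_iterations=self.baseline_iterations,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        axis = self.axis if self.axis is not None else default_axis_for(X.shape[1])
        self.axis_ = axis
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if not hasattr(self, "axis_"):
            self.fit(X)
        config = self._config()
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            spec = RamanSpectrum(self.axis_, X[i], stage="raw")
            out[i] = preprocess_spectrum(spec, config).intensities
        return out


def default_axis_for(p: int) -> WavenumberAxis:
    """Evenly spaced axis over the default window with ``p`` points."""
    return WavenumberAxis(np.linspace(DEFAULT_AXIS_MIN, DEFAULT_AXIS_MAX, p))
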