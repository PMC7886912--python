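"""Synthetic spectra with known ground truth.

No single-cell Raman dataset accompanies the radio-sensitivity study this
package operationalizes, so every pipeline stage is exercised against
generated data that emulates the study design: three cell lines (two
radio-resistant, one radio-sensitive), single radiation fractions of
0-10 Gy, days 1-3 post-irradiation, three replicate cultures, and twenty
cells per sample, recorded over a 450-1800 cm^-1 window.

The generator plants the qualitative structure the analysis is meant to
recover:

* a glycogen-like factor whose score rises with dose in the resistant
  lines only;
* a glucose-like factor negatively coupled to glycogen within the
  resistant lines (glycogen is polymerized glucose);
* a phosphatidylcholine-like factor separating the sensitive line from
  the resistant ones (the discriminative variable for classification);
* smaller line effects on asparagine-, arginine-, lactose- and citric
  acid-like factors, and a pool of nuisance factors with pure noise.

Scores carry multiplicative lognormal noise (non-negativity preserved)
and are rescaled so every factor's grand mean is exactly 1, the same
convention the factorization imposes on its fitted scores, making truth
and fit directly comparable.  Raw-mode synthesis adds a smooth random
polynomial fluorescence baseline, additive Gaussian detector noise, and
Bernoulli single-pixel cosmic spikes, producing input for the full
preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import RamanMFError
from .spectra import BasisLibrary, SpectralDataset, WavenumberAxis, default_axis

RESISTANT_LINES = ("H460", "MCF7")
SENSITIVE_LINE = "LNCaP"
DEFAULT_LINES = ("H460", "MCF7", "LNCaP")
DEFAULT_DOSES = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
DEFAULT_DAYS = (1, 2, 3)

#: Stand-in labels for a 30-chemical reference library.  The first ten
#: are the biochemicals the downstream analysis discusses by name; the
#: rest are plausible cellular constituents acting as nuisance factors.
DEFAULT_CHEMICALS = (
    "glycogen", "glucose", "phosphatidylcholine", "asparagine", "arginine",
    "lactose", "citric_acid", "glutamic_acid", "glutathione",
    "phosphatidylserine", "alanine", "glycine", "valine", "leucine",
    "tyrosine", "tryptophan", "phenylalanine", "cholesterol", "triolein",
    "dna", "rna", "actin", "albumin", "collagen", "fructose", "sucrose",
    "lactic_acid", "pyruvate", "creatine", "taurine",
)


# ---------------------------------------------------------------------------
# basis library
# ---------------------------------------------------------------------------


def _peak(axis: np.ndarray, center: float, fwhm: float, lorentzian: bool) -> np.ndarray:
    if lorentzian:
        x = (axis - center) / (fwhm / 2.0)
        return 1.0 / (1.0 + x ** 2)
    x = (axis - center) / (fwhm / 2.3548)
    return np.exp(-0.5 * x ** 2)


def generate_basis_library(m: int = 30, axis: WavenumberAxis | None = None,
                           peaks_per_basis: tuple[int, int] = (3, 10),
                           width_range: tuple[float, float] = (5.0, 30.0),
                           band_range: tuple[float, float] = (480.0, 1700.0),
                           n_canonical: int = 26,
                           lorentzian_fraction: float = 0.0,
                           max_correlation: float = 0.8,
                           seed: int = 0,
                           names=None) -> BasisLibrary:
    """Random unit-area reference spectra with shared canonical bands.

    Vibrational bands of biological molecules concentrate at recurring
    frequencies (ring breathing, CH deformation, amide modes, ...), so
    the generator first lays down ``n_canonical`` canonical band
    positions — stratified over ``band_range`` with jitter, which both
    mimics how real band inventories spread across the fingerprint
    region and guarantees quiet inter-band gaps that anchor baseline
    estimation.  Each chemical then draws 3-10 of those positions (with
    a few cm^-1 of chemical shift), a bandwidth (FWHM, cm^-1) from
    ``width_range`` and a random intensity per band.  Peaks are
    Gaussian by default; ``lorentzian_fraction`` mixes in Lorentzian
    lineshapes, whose heavy tails raise the inter-band floor.

    ``band_range`` defaults inside the 450-1800 cm^-1 window, matching
    the quiet margins real fingerprint spectra show at the window edges.
    Rows are redrawn until every pairwise Pearson correlation stays at
    or below ``max_correlation``, so the library is well conditioned for
    NNLS.  Deterministic for a fixed seed.
    """
    if m < 1:
        raise RamanMFError("library size m must be >= 1")
    axis = axis if axis is not None else default_axis()
    if names is None:
        names = [DEFAULT_CHEMICALS[j] if j < len(DEFAULT_CHEMICALS)
                 else f"chemical_{j + 1}" for j in range(m)]
    rng = np.random.default_rng(seed)
    grid = axis.values
    lo, hi = axis.span
    band_lo, band_hi = max(band_range[0], lo), min(band_range[1], hi)
    base = np.linspace(band_lo, band_hi, n_canonical)
    spacing = base[1] - base[0]
    canonical = base + rng.uniform(-0.25, 0.25, n_canonical) * spacing
    k_max = min(peaks_per_basis[1], n_canonical)
    rows: list[np.ndarray] = []
    max_attempts = 500
    for j in range(m):
        for attempt in range(max_attempts):
            n_peaks = int(rng.integers(peaks_per_basis[0], k_max + 1))
            centers = (rng.choice(canonical, size=n_peaks, replace=False)
                       + rng.uniform(-3.0, 3.0, n_peaks))
            row = np.zeros_like(grid)
            for center in centers:
                width = rng.uniform(*width_range)
                amp = rng.uniform(0.2, 1.0)
                row += amp * _peak(grid, center, width,
                                   rng.random() < lorentzian_fraction)
            row /= np.trapezoid(row, grid)
            if all(abs(np.corrcoef(row, r)[0, 1]) <= max_correlation for r in rows):
                rows.append(row)
                break
        else:
            raise RamanMFError(
                f"could not draw basis {j + 1} with pairwise correlation "
                f"<= {max_correlation} in {max_attempts} attempts"
            )
    return BasisLibrary(list(names), np.array(rows), axis)


# ---------------------------------------------------------------------------
# experimental design and score trends
# ---------------------------------------------------------------------------


def generate_design(lines=DEFAULT_LINES, doses=DEFAULT_DOSES, days=DEFAULT_DAYS,
                    replicates: int = 3, cells_per_sample: int = 20) -> pd.DataFrame:
    """Full-factorial metadata table, one row per cell spectrum."""
    if len(doses) == 0:
        raise RamanMFError("dose set must be non-empty")
    if min(replicates, cells_per_sample, len(lines), len(days)) < 1:
        raise RamanMFError("all design counts must be >= 1")
    records = []
    for line in lines:
        for dose in doses:
            for day in days:
                for rep in range(1, replicates + 1):
                    for cell in range(1, cells_per_sample + 1):
                        records.append({
                            "cell_line": line,
                            "dose_gy": float(dose),
                            "day": int(day),
                            "replicate": f"r{rep}",
                            "cell_id": f"{line}_{dose:g}Gy_day{day}_r{rep}_c{cell:03d}",
                        })
    return pd.DataFrame.from_records(records)


def _per_row(value, lines: pd.Series, default=0.0) -> np.ndarray:
    """Broadcast a scalar or per-line dict over metadata rows."""
    if isinstance(value, dict):
        return lines.map(lambda ln: value.get(ln, default)).to_numpy(dtype=float)
    return np.full(len(lines), float(value))


@dataclass
class FactorTrend:
    """Deterministic trend of one factor's mean score.

    mean = baseline * line_multiplier * (1 + dose_slope * dose)
                                      * (1 + day_slope * day)

    ``dose_slope``/``day_slope`` may be scalars or per-line dicts (units:
    fractional change per Gy and per day).  A coupled factor instead
    draws its fluctuations correlated with its target factor's within
    each line (see :func:`simulate_score_trends`).
    """

    baseline: float = 1.0
    dose_slope: float | dict = 0.0
    day_slope: float | dict = 0.0
    line_multipliers: dict = field(default_factory=dict)
    couple_to: str | None = None
    couple_r: float | dict = 0.0
    coupling_amplitude: float = 0.25


@dataclass
class TrendConfig:
    """Per-factor trends; factors not listed default to flat noise."""

    factors: dict[str, FactorTrend] = field(default_factory=dict)

    def get(self, name: str) -> FactorTrend:
        return self.factors.get(name, FactorTrend())


def study_analog_trends() -> TrendConfig:
    """Default study-analog preset (see module docstring)."""
    return TrendConfig({
        "glycogen": FactorTrend(
            dose_slope={"H460": 0.10, "MCF7": 0.07, "LNCaP": 0.0},
            day_slope={"H460": 0.04, "MCF7": 0.04, "LNCaP": 0.0},
        ),
        "glucose": FactorTrend(
            line_multipliers={"MCF7": 1.3, "LNCaP": 1.15},
            couple_to="glycogen",
            couple_r={"H460": -0.7, "MCF7": -0.7, "LNCaP": 0.0},
        ),
        "phosphatidylcholine": FactorTrend(
            line_multipliers={"H460": 1.5, "MCF7": 1.4, "LNCaP": 0.55},
        ),
        "asparagine": FactorTrend(
            line_multipliers={"MCF7": 1.3, "LNCaP": 0.8},
            dose_slope={"H460": -0.03},
        ),
        "arginine": FactorTrend(line_multipliers={"LNCaP": 1.25}),
        "lactose": FactorTrend(
            line_multipliers={"H460": 1.4}, dose_slope={"H460": -0.04},
        ),
        "citric_acid": FactorTrend(dose_slope={"H460": -0.04, "MCF7": -0.04}),
        "glutamic_acid": FactorTrend(line_multipliers={"MCF7": 1.2}),
        "glutathione": FactorTrend(line_multipliers={"MCF7": 0.8}),
        "phosphatidylserine": FactorTrend(line_multipliers={"LNCaP": 0.85}),
    })


def glycogen_dominated_trends() -> TrendConfig:
    """Preset where the glycogen-like factor carries most planted variance."""
    return TrendConfig({
        "glycogen": FactorTrend(
            dose_slope={"H460": 0.18, "MCF7": 0.15, "LNCaP": 0.0},
            day_slope={"H460": 0.05, "MCF7": 0.05, "LNCaP": 0.0},
        ),
    })


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    true_scores: np.ndarray          # (n, k), grand mean exactly 1 per factor
    library: BasisLibrary
    design: pd.DataFrame
    trend_config: TrendConfig
    noise_cv: float
    seed: int
    spike_mask: np.ndarray | None = None   # set by raw-mode synthesis

    @property
    def factor_names(self) -> list[str]:
        return list(self.library.names)

    def area_scaled_scores(self) -> np.ndarray:
        """Truth on the scale the model can recover.

        The factorization sees area-normalized spectra, so the
        recoverable quantity is each score divided by the clean
        spectrum's total area (relative chemical contribution).
        """
        clean = self.true_scores @ self.library.B
        areas = np.trapezoid(clean, self.library.axis.values, axis=1)
        return self.true_scores / areas[:, None]


def simulate_score_trends(design: pd.DataFrame, library: BasisLibrary,
                          trends: TrendConfig, noise_cv: float = 0.05,
                          seed: int = 0) -> SyntheticTruth:
    """Draw per-cell true scores for every library factor.

    Uncoupled factors: mean trend times lognormal(1, CV) noise.  Coupled
    factors: within each line, fluctuations are drawn with the configured
    Pearson correlation against the (standardized) target factor, so the
    planted correlation is exact in population; the factor's own
    deterministic dose/day trend must be flat for the guarantee to hold.
    Finally each factor is rescaled to grand mean exactly 1.
    """
    n = len(design)
    names = library.names
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    lines = design["cell_line"]
    dose = design["dose_gy"].to_numpy(dtype=float)
    day = design["day"].to_numpy(dtype=float)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))

    scores = np.empty((n, len(names)))
    order = sorted(range(len(names)),
                   key=lambda j: trends.get(names[j]).couple_to is not None)
    for j in order:
        trend = trends.get(names[j])
        mult = _per_row(trend.line_multipliers, lines, default=1.0)
        mean = (trend.baseline * mult
                * (1.0 + _per_row(trend.dose_slope, lines) * dose)
                * (1.0 + _per_row(trend.day_slope, lines) * day))
        if np.any(mean <= 0):
            raise RamanMFError(
                f"trend configuration forces non-positive mean score for "
                f"{names[j]!r}"
            )
        if trend.couple_to is None:
            noise = np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma ** 2) \
                if sigma > 0 else np.ones(n)
            scores[:, j] = mean * noise
        else:
            if trend.couple_to not in names:
                raise RamanMFError(
                    f"{names[j]!r} couples to unknown factor {trend.couple_to!r}"
                )
            target = scores[:, names.index(trend.couple_to)]
            rho_row = _per_row(trend.couple_r, lines)
            gamma = trend.coupling_amplitude
            vals = np.empty(n)
            for line in lines.unique():
                idx = np.flatnonzero((lines == line).to_numpy())
                rho = float(rho_row[idx[0]])
                t = target[idx]
                t_sd = t.std()
                u = (t - t.mean()) / t_sd if t_sd > 0 else np.zeros(idx.size)
                e = rng.standard_normal(idx.size)
                v = rho * u + np.sqrt(max(0.0, 1.0 - rho ** 2)) * e
                vals[idx] = mean[idx] * (1.0 + gamma * v)
            scores[:, j] = np.clip(vals, 1e-9, None)
    scores /= scores.mean(axis=0)
    return SyntheticTruth(scores, library, design.reset_index(drop=True),
                          trends, noise_cv, seed)


# ---------------------------------------------------------------------------
# spectral synthesis
# ---------------------------------------------------------------------------


def synthesize_spectra(truth: SyntheticTruth, raw: bool = False,
                       additive_noise_sd: float = 0.003,
                       baseline_amplitude: tuple[float, float] = (0.5, 2.0),
                       spike_probability: float = 0.1,
                       spike_magnitude: tuple[float, float] = (20.0, 100.0),
                       seed: int | None = None) -> SpectralDataset:
    """Mix true scores with the basis library into spectra.

    With ``raw=False`` the clean mixture ``true_scores @ B`` is returned
    exactly.  With ``raw=True`` each spectrum additionally receives a
    smooth order-3 polynomial fluorescence baseline scaled to 0.5-2x the
    mean signal, additive Gaussian noise (``additive_noise_sd`` as a
    fraction of the mean clean intensity), and with probability
    ``spike_probability`` one cosmic-ray pixel at 20-100x the spectrum's
    median intensity; the planted spike mask is stored on ``truth``.
    """
    B = truth.library.B
    scores = truth.true_scores
    if scores.shape[1] != B.shape[0]:
        raise RamanMFError(
            f"{scores.shape[1]} score columns vs {B.shape[0]} library rows"
        )
    X = scores @ B
    axis = truth.library.axis
    if not raw:
        return SpectralDataset(X, axis, truth.design.copy(), stage="baselined")

    rng = np.random.default_rng(
        np.random.SeedSequence([truth.seed if seed is None else seed, 11]))
    n, p = X.shape
    t = np.linspace(0.0, 1.0, p)
    mean_signal = X.mean()
    out = X.copy()
    # fluorescence baseline: random positive cubic, scaled per spectrum
    coeffs = rng.uniform(0.1, 1.0, size=(n, 4))
    poly = coeffs @ np.vstack([np.ones_like(t), t, t ** 2, t ** 3])
    amp = rng.uniform(*baseline_amplitude, size=n) * X.mean(axis=1)
    out += poly / poly.mean(axis=1, keepdims=True) * amp[:, None]
    # detector noise
    out += rng.normal(0.0, additive_noise_sd * mean_signal, size=(n, p))
    # cosmic spikes
    spike_mask = np.zeros((n, p), dtype=bool)
    hit = rng.random(n) < spike_probability
    pixels = rng.integers(0, p, size=n)
    mags = rng.uniform(*spike_magnitude, size=n)
    for i in np.flatnonzero(hit):
        local = np.median(out[i])
        out[i, pixels[i]] += mags[i] * max(local, mean_signal * 0.1)
        spike_mask[i, pixels[i]] = True
    truth.spike_mask = spike_mask
    return SpectralDataset(out, axis, truth.design.copy(), stage="raw")


# ---------------------------------------------------------------------------
# one-call presets
# ---------------------------------------------------------------------------


def study_analog_dataset(seed: int = 0, cells_per_sample: int = 20,
                         noise_cv: float = 0.05, raw: bool = True,
                         axis: WavenumberAxis | None = None,
                         trends: TrendConfig | None = None):
    """Full study-analog bundle: (dataset, truth, library).

    Defaults reproduce the nominal design: 3 lines x 6 doses x 3 days x
    3 replicates x ``cells_per_sample`` cells = 3240 spectra at 20
    cells/sample, over a 30-chemical library plus planted trends.
    """
    axis = axis if axis is not None else default_axis()
    library = generate_basis_library(30, axis=axis, seed=seed)
    design = generate_design(cells_per_sample=cells_per_sample)
    trends = trends if trends is not None else study_analog_trends()
    truth = simulate_score_trends(design, library, trends,
                                  noise_cv=noise_cv, seed=seed)
    dataset = synthesize_spectra(truth, raw=raw)
    return dataset, truth, library


def glycogen_dominated_dataset(seed: int = 0, cells_per_sample: int = 5,
                               noise_cv: float = 0.02, raw: bool = False):
    """Smaller preset where the glycogen-like factor dominates variance."""
    return study_analog_dataset(seed=seed, cells_per_sample=cells_per_sample,
                                noise_cv=noise_cv, raw=raw,
                                trends=glycogen_dominated_trends())
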