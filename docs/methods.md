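# Methods

## Model

The core decomposition approximates a matrix of preprocessed
single-cell Raman spectra `X` (n × p, non-negative, each row with unit
area under the curve) as `X ≈ W A S`:

* `S` (k × p): non-negative basis spectra. Rows 1..m are fixed,
  bit-for-bit, to a library of reference chemical spectra processed
  with the same normalization as the cell spectra; rows m+1..k
  (`n_free`, default 1) are estimated from the data. The single
  unconstrained factor absorbs structured signal the library does not
  span — unmodelled chemistry or residual background common to many
  spectra.
* `W` (n × k): non-negative scores, the contribution of each factor to
  each spectrum.
* `A`: positive diagonal. After convergence, `A_jj` is set to the mean
  of raw score column j and `W` is divided column-wise by it, so every
  non-degenerate factor has mean score exactly 1. This is a pure
  reparameterization — `W·A·S` equals the unscaled fit — and makes
  scores comparable across factors and against the generator's truth
  convention.

Assumptions: spectra are non-negative linear mixtures of the library
chemicals on a shared wavenumber axis; scores carry the biology; the
per-spectrum scale is not informative (removed by area normalization,
so a score is a *relative* contribution).

### Optimizer

Block-coordinate alternating non-negative least squares. Each W row
solves `min ||x_i − w S||², w ≥ 0` exactly (active-set NNLS after a
Cholesky reduction of the basis Gram matrix, making the per-row cost
independent of the number of wavenumbers); each free basis column
solves the transposed subproblem given W. Because every block update is
an exact minimizer, the squared Frobenius objective is non-increasing
at every iteration with no step-size tuning; the trace is recorded and
asserted in the test suite (with a floor of 1e-14·‖X‖² on the
comparison, since an exactly-fit objective sits at machine-noise level
where monotonicity is meaningless).

Initialization is deterministic: W by NNLS against the fixed library;
free rows from the non-negative part (whichever sign has the larger
norm) of the leading right singular vectors of the initial residual,
scaled to unit sum. Convergence: relative objective change below 1e-8
(default) or 500 iterations; non-convergence sets a flag rather than
raising. With exact block solves the fit typically converges in a
handful of iterations. All-zero factors are flagged degenerate, get
`A_jj = 1`, and are retained so column counts stay stable. If the
basis Gram matrix is singular (zero or collinear rows) the solver
falls back to full-size per-row NNLS.

The "group" half of the original group- and basis-restricted method
(group restrictions on W) is not implemented; nothing in this
workflow exercises it.

## Preprocessing

Fixed order, enforced through explicit stage tags:
despike → baseline subtraction → clip negatives → area-normalize.

* **Cosmic-ray removal.** Candidates come from the modified z-score of
  first differences (threshold 8, window 11); the robust MAD scale is
  floored at 1e-6 of the largest difference so numerically flat
  regions of noiseless spectra do not register as outliers. Candidates
  are grouped into contiguous runs: a spike of w pixels yields w + 2
  candidates (one guard pixel each side), so runs longer than
  `max_spike_width + 2` (default spike width 2) are rejected — an
  intense but genuine Raman band spans many pixels and must not be
  repaired. A second tier catches spikes superimposed on band flanks,
  where the run-length gate would hide them: a pixel standing above
  its 5-pixel median-filtered surroundings by more than the spectrum's
  robust amplitude (1st–99th percentile range of the filtered
  spectrum) can only be a cosmic ray, since rays are tens of times the
  median intensity and at most two pixels wide. Repair is linear
  interpolation from unflagged neighbours; off-mask pixels are
  bitwise untouched.
* **Baseline.** Asymmetric least squares (Whittaker smoother with a
  second-difference penalty, pentadiagonal banded solve), smoothness
  1e5, asymmetry 0.001, 10 reweighting iterations. The small asymmetry
  makes the fit interpolate stiffly across band clusters while
  anchoring in the quiet inter-band gaps; 0.001 proved markedly more
  accurate than the more common 0.01 on dense multi-band spectra,
  whose signal otherwise pulls the baseline upward.
* **Clip + area.** Negative residuals are clipped to zero (the
  factorization requires non-negative X), then each spectrum is
  divided by its trapezoidal integral over the wavenumber axis —
  well-defined on non-uniform grids. Normalization is idempotent and
  scale-invariant; all-zero spectra raise a distinct error carrying
  the cell identifier.

Library spectra get the identical resample → clip → normalize
treatment, so scores are not confounded by reference-spectrum scale.

## Synthetic data

The generator emulates the study design so every stage is testable
with ground truth: 3 cell lines × doses {0, 2, 4, 6, 8, 10} Gy ×
days 1–3 × 3 replicate cultures × 20 cells per sample (3240 spectra),
over a 450–1800 cm⁻¹ window at 2 cm⁻¹ spacing (676 points).

**Library.** 30 unit-area reference spectra, each a sum of 3–10 peaks
with bandwidths (FWHM) of 5–30 cm⁻¹ and random intensities. Peak
positions are drawn from a shared inventory of 26 canonical band
positions, stratified with jitter over 480–1700 cm⁻¹. Both choices are
deliberate emulations of real vibrational spectra: biological Raman
bands recur at characteristic frequencies spread across the
fingerprint region, and fingerprint windows have quiet margins at
their edges. They also make baseline estimation well-posed — the
stratified inventory guarantees inter-band gaps everywhere, which is
exactly what anchors an asymmetric-least-squares baseline on real
spectra. Purely random band placement instead yields, for some draws,
long anchor-free spans where any envelope estimator bows into the
signal; that regime is a known limitation for dense spectra, not
something the generator should manufacture by accident. Lineshapes are
Gaussian by default (`lorentzian_fraction` exposes Voigt-like mixing;
heavy Lorentzian tails raise the inter-band floor and degrade baseline
identifiability). Rows are redrawn until all pairwise Pearson
correlations are ≤ 0.8.

**Score trends.** Per factor, mean = baseline × line-multiplier ×
(1 + dose-slope·dose) × (1 + day-slope·day), times lognormal
multiplicative noise (CV 5% by default — keeps scores positive).
The study-analog preset plants: glycogen rising with dose and day in
the resistant lines only (slopes 0.10 and 0.07 per Gy for H460 and
MCF7); glucose negatively coupled to glycogen at r = −0.7 within each
resistant line; phosphatidylcholine separating the sensitive line
(multipliers 1.5/1.4 resistant vs 0.55 sensitive) — the intended
discriminative variable; milder line effects on asparagine, arginine,
lactose, citric acid, glutamic acid, glutathione and
phosphatidylserine; the remaining factors are pure noise. A coupled
factor draws its fluctuations as a linear blend of the standardized
target factor and independent noise within each line, which makes the
planted correlation exact in population; its own deterministic dose
trend must be flat for that guarantee (the dose dependence arrives
through the coupling). After generation every factor is rescaled to
grand mean exactly 1, mirroring the model's convention so truth and
fitted scores are directly comparable.

**Raw synthesis.** Clean mixtures `truth · B` receive, per spectrum: a
random positive cubic fluorescence baseline scaled to 0.5–2× the mean
signal; additive Gaussian detector noise with SD 0.3% of the mean
clean intensity (a high-quality confocal acquisition; the recovery
experiments are reported at this level); and with probability 0.1 a
single-pixel cosmic spike at 20–100× the spectrum's median intensity.
The planted spike mask is kept for despiker validation.

Because spectra are area-normalized before factorization, the
recoverable truth is each score divided by its clean spectrum's area
(`SyntheticTruth.area_scaled_scores`); Pearson recovery correlations
are computed against that scale.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real cellular spectra are denser than the
canonical-band mixtures (their baseline correction carries a larger,
chemistry-correlated bias); real reference libraries contain strongly
correlated chemicals (glucose vs glycogen share most bands, where
synthetic bases are decorrelated to ≤ 0.8); lineshapes, instrument
response, detector etaloning and wavenumber-calibration drift are not
modelled; and class separations are planted to be clean, so the
near-perfect classification accuracy on synthetic data is a check of
the machinery, not a claim about biological effect sizes.

## Analysis choices

* PCA is computed on preprocessed (area-normalized) spectra by full
  SVD with column-mean centering; the sign of each loading is fixed by
  making its largest-magnitude element positive. Loadings are matched
  to library chemicals by |Pearson r| — absolute value because a PC's
  sign is arbitrary (published loading overlays are routinely
  inverted).
* Group summaries report mean ± SE (sample SD / √n) per (line, dose,
  day); singleton groups are flagged rather than reporting SE 0.
* The glucose–glycogen association uses Pearson correlation (the
  association is modelled as linear), per cell line.
* Dosed-vs-control comparisons use Welch's two-sample t-test against
  the same-day 0 Gy group of the same line — chosen for robustness to
  unequal variances, with Mann-Whitney as a configurable alternative.
  No multiple-testing correction is applied by default;
  Benjamini-Hochberg is available by flag. Missing controls raise an
  error naming the (line, day).

## Classification

Labels map cell lines to classes (H460, MCF7 → radio-resistant;
LNCaP → radio-sensitive; mapping configurable). The split is random
*stratified* 75/25 — stratification stabilizes the 2:1 class imbalance.
The forest uses 200 trees and 5 variables per split, with out-of-bag
scoring; identical seeds give identical splits and forests.

MDA (mean decrease accuracy) is permutation importance computed on the
held-out set: for each variable the test column is permuted 10 times
and the drop from unpermuted accuracy is averaged, with all permuted
copies of a variable scored in one batched predict call. The reported
table averages 10 independently seeded split+fit repeats (seed ladder
`seed + i`, recorded in the report); it covers all score columns
including the unconstrained factor. The in-package implementation is
cross-checked against scikit-learn's `permutation_importance` in the
test suite. Mean decrease in node impurity is available as an optional
secondary measure.

Sensitivity and specificity depend on which class is declared positive,
so `classification_report` emits the metric set for both orientations;
the false-positive share is reported as a percentage of the whole test
set. Displayed values are rounded to one decimal; stored values are
full precision.

The OOB hyperparameter grid spans 100–2000 trees (step 100) × 1–30
variables per split, each cell averaged over 5 seeded fits; tests
exercise reduced ranges.

## Problem sizes

The test suite and acceptance script run: truth recovery at the full
nominal design (3240 spectra through raw preprocessing and a 31-factor
fit); PCA and correlation analogs at 810 and ~600 spectra; the
classification analog at 810 spectra across 20 seeds × 10 models; the
type-I-error calibration with 1000 null simulations at n = 20 per
group; and solver/monotonicity checks on 120 small random problems.

## Known limitations

* Baseline correction on spectra without usable inter-band gaps
  (dense forests of overlapping bands) biases scores; the unconstrained
  factor absorbs only the *consistent* part of that bias.
* The per-spectrum despiker cannot distinguish a cosmic ray from a
  genuine one-pixel feature when the spectrum has no noise floor and
  the ray is smaller than the spectral amplitude; on realistic raw
  spectra (background-lifted median) detection is reliable anywhere,
  including on band flanks.
* Scores are relative contributions (area-normalization removes
  per-cell scale); absolute concentration changes that move all
  chemicals together are invisible.
* The free-factor update can only *add* non-negative signal; it cannot
  compensate over-subtraction introduced upstream.
* `n_free > 1` is supported but factors are exchangeable (no ordering
  constraint beyond initialization).
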