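# ramanmf

Basis-restricted non-negative matrix factorization for single-cell
Raman spectra, with the downstream statistics used to profile metabolic
radiation response in tumour cell lines.

## The problem

Single-cell Raman microspectroscopy records a vibrational fingerprint
of every cell's biochemical content. Unsupervised decompositions such
as PCA separate irradiated from unirradiated cells, but each principal
component mixes many biochemicals (and carries negative features), so
score trends are hard to attribute to a specific metabolite. A
semi-supervised alternative constrains the factorization to a library
of measured reference spectra: every factor *is* a chemical, and its
score is directly the contribution of that chemical to the cell's
spectrum.

This package implements that pipeline for the radio-sensitivity
setting: three tumour cell lines (H460 lung and MCF7 breast,
radio-resistant; LNCaP prostate, radio-sensitive), single radiation
fractions of 0–10 Gy, spectra on days 1–3 post-irradiation. Because no
single-cell spectra are publicly deposited for this design, the package
ships a first-class synthetic generator that emulates the study
(including the glycogen dose response of resistant lines, the
glucose–glycogen anticorrelation, and a line-separating
phosphatidylcholine factor) so the entire pipeline is testable against
known ground truth.

## The model

Preprocessed spectra are collected in a non-negative matrix `X`
(n spectra × p wavenumbers, each row area-normalized to 1) and
decomposed as

```
X  ≈  W A S
```

* `S` (k × p) — non-negative basis spectra. The first `m` rows are
  **fixed** to the reference chemical library (30 biochemicals by
  default); the remaining `n_free` rows (1 by default) are estimated
  from the data and absorb signal the library does not span.
* `W` (n × k) — non-negative scores: the contribution of each chemical
  to each cell spectrum.
* `A` — positive diagonal scaling chosen so that every factor's mean
  score over the dataset equals exactly 1; `W·A·S` is identical to the
  unscaled fit.

The optimizer is block-coordinate alternating non-negative least
squares: every W row and every free basis column is an exactly-solved
NNLS subproblem, so the squared-error objective is monotone
non-increasing and no step sizes need tuning. With `n_free = 0` the fit
is exactly row-wise NNLS against the library.

Downstream, the package provides PCA validation (matching PC loadings
to library spectra by absolute Pearson correlation), per-(line, dose,
day) score summaries with standard errors, Pearson association between
chemical scores, Welch tests of each dosed group against its same-day
unirradiated control, and a random-forest classifier of
radio-sensitivity (200 trees, 5 variables per split, stratified 75/25
split) with permutation importance (mean decrease accuracy, averaged
over 10 repeated split+fit cycles) and an out-of-bag error
hyperparameter grid.

## Worked example

```python
import numpy as np
from ramanmf import synthetic, preprocess_dataset, fit_gbrnmf, score_table
from ramanmf.analysis import correlate_scores
from ramanmf.classify import classification_report

# simulate the study design: 3 cell lines x 6 doses x 3 days x 3
# replicates x 5 cells, 30-chemical library plus planted trends
dataset, truth, library = synthetic.study_analog_dataset(
    seed=7, cells_per_sample=5, raw=True)
print(f"raw spectra: {dataset.n_spectra} x {dataset.X.shape[1]}")

processed = preprocess_dataset(dataset)          # despike, baseline, normalize
model = fit_gbrnmf(processed, library, n_free=1)
print(f"factors: {len(model.factor_names_)} "
      f"(converged in {model.n_iter_} iterations)")

scores = score_table(model, processed)
r = correlate_scores(scores, "glucose", "glycogen",
                     subset={"cell_line": "H460"})
print(f"glucose~glycogen in H460: r = {r.r:.2f} (p = {r.p_value:.1e}, n = {r.n})")

report = classification_report(scores, scores.meta, n_models=10, seed=17)
m = report.metrics["radiosensitive"]
print(f"test accuracy: {m['accuracy_pct']:.1f}%  "
      f"false positives: {m['false_positive_pct_of_total']:.1f}% of test set")
for _, row in report.importance.nlargest(3, "mda_mean").iterrows():
    print(f"  MDA {row.variable}: {row.mda_mean:.3f} +/- {row.mda_sd:.3f}")
```

Output:

```
raw spectra: 810 x 676
factors: 31 (converged in 2 iterations)
glucose~glycogen in H460: r = -0.69 (p = 2.5e-39, n = 270)
test accuracy: 100.0%  false positives: 0.0% of test set
  MDA phosphatidylcholine: 0.009 +/- 0.007
  MDA arginine: 0.002 +/- 0.003
  MDA glycogen: 0.000 +/- 0.000
```

Reading the numbers: the planted negative glucose–glycogen coupling in
the resistant H460 line is recovered (r = −0.69 vs the planted −0.7);
the forest separates radio-sensitive from radio-resistant cells
perfectly on held-out data; and permuting the phosphatidylcholine
score column costs the model the most held-out accuracy — it is the
discriminative variable, exactly as planted.

## Command line

```bash
ramanmf simulate   --outdir sim --seed 1          # synthetic dataset + truth
ramanmf preprocess --matrix sim/spectra.csv --metadata sim/metadata.csv --outdir pre
ramanmf fit        --matrix pre/preprocessed.csv --metadata pre/metadata.csv \
                   --library sim/library/library.csv --outdir fit
ramanmf classify   --scores fit/scores.csv --trees 200 --mtry 5 --outdir rf
ramanmf run        --config run.yaml --outdir out  # full pipeline, one config
```

`ramanmf run` validates a YAML config up front (unknown keys rejected),
executes simulate/ingest → preprocess → fit → analyze → classify, and
records seeds, settings and a config hash in every output, so identical
configs reproduce byte-identical score tables.

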