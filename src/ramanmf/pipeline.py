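"""End-to-end pipeline: simulate/ingest -> preprocess -> fit -> analyze -> classify.

One validated configuration drives one run directory.  Every stage
records its settings and seeds in a JSON provenance sidecar, CSV outputs
carry a header comment with the package version and the configuration
hash, and re-running an identical configuration reproduces identical
files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import __version__
from .analysis import (
    compare_to_control,
    correlate_scores,
    match_loading_to_basis,
    run_pca,
    score_summary,
)
from .classify import DEFAULT_CLASS_MAPPING, classification_report
from .errors import ConfigError
from .gbrnmf import GBRNMF, fit_gbrnmf, score_table
from .spectra import (
    PreprocessConfig,
    default_axis,
    load_dataset,
    load_library_manifest,
    preprocess_dataset,
    save_dataset,
    save_library,
)
from . import synthetic

_FLOAT_FMT = "%.10g"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Strict):
    preset: str = "study-analog"          # or "glycogen-dominated"
    cells_per_sample: int = 20
    noise_cv: float = 0.05
    raw: bool = True
    seed: int = 0


class InputSection(_Strict):
    matrix: str
    metadata: str
    library_manifest: str
    stage: str = "raw"


class PreprocessSection(_Strict):
    despike_window: int = 11
    despike_z_threshold: float = 8.0
    despike_max_width: int = 2
    baseline_smoothness: float = 1e5
    baseline_asymmetry: float = 0.001
    baseline_iterations: int = 10


class ModelSection(_Strict):
    n_free: int = 1
    max_iter: int = 500
    tol: float = 1e-8
    seed: int = 0


class AnalysisSection(_Strict):
    summary_factors: list[str] | None = None
    correlation_pairs: list[tuple[str, str]] = [("glucose", "glycogen")]
    correlate_by_line: bool = True
    control_factors: list[str] = []
    alpha: float = 0.05
    n_components: int = 2


class ClassifySection(_Strict):
    mapping: dict[str, str] = dict(DEFAULT_CLASS_MAPPING)
    n_trees: int = 200
    mtry: int = 5
    split_fraction: float = 0.75
    n_models: int = 10
    n_permutation_repeats: int = 10
    seed: int = 17


class PipelineConfig(_Strict):
    """Schema-validated configuration of a full run."""

    simulate: SimulateSection | None = None
    input: InputSection | None = None
    preprocess: PreprocessSection = PreprocessSection()
    model: ModelSection = ModelSection()
    analysis: AnalysisSection = AnalysisSection()
    classify: ClassifySection = ClassifySection()

    @model_validator(mode="after")
    def _one_source(self):
        if (self.simulate is None) == (self.input is None):
            raise ValueError("exactly one of 'simulate' or 'input' is required")
        return self

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def _write_csv(frame: pd.DataFrame, path: Path, tag: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ramanmf {__version__} config={tag}\n")
        frame.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages; returns a dict of in-memory results.

    Writes into ``outdir``: the basis library, preprocessed dataset,
    model archive with JSON sidecar, score table, PCA loadings and basis
    matches, group summaries, correlations, optional vs-control tests,
    the random-forest report, and a provenance record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)

    # --- acquire data ------------------------------------------------------
    truth = None
    if config.simulate is not None:
        sim = config.simulate
        if sim.preset == "study-analog":
            dataset, truth, library = synthetic.study_analog_dataset(
                seed=sim.seed, cells_per_sample=sim.cells_per_sample,
                noise_cv=sim.noise_cv, raw=sim.raw)
        elif sim.preset == "glycogen-dominated":
            dataset, truth, library = synthetic.glycogen_dominated_dataset(
                seed=sim.seed, cells_per_sample=sim.cells_per_sample,
                noise_cv=sim.noise_cv, raw=sim.raw)
        else:
            raise ConfigError(f"unknown simulation preset {sim.preset!r}")
        note(f"simulated preset={sim.preset} n={dataset.n_spectra} "
             f"seed={sim.seed}")
    else:
        inp = config.input
        axis = default_axis()
        library = load_library_manifest(inp.library_manifest, axis)
        dataset = load_dataset(inp.matrix, inp.metadata, stage=inp.stage)
        note(f"loaded n={dataset.n_spectra} from {inp.matrix}")
    save_library(library, outdir / "library")

    # --- preprocess --------------------------------------------------------
    if dataset.stage == "raw":
        pp = config.preprocess
        dataset = preprocess_dataset(dataset, PreprocessConfig(
            despike_window=pp.despike_window,
            despike_z_threshold=pp.despike_z_threshold,
            despike_max_width=pp.despike_max_width,
            baseline_smoothness=pp.baseline_smoothness,
            baseline_asymmetry=pp.baseline_asymmetry,
            baseline_iterations=pp.baseline_iterations,
        ))
        note("preprocessed: despike -> baseline -> clip -> normalize")
    elif dataset.stage != "normalized":
        from .spectra import SpectralDataset, normalize_area
        rows = np.array([
            normalize_area(dataset.spectrum(i)).intensities
            for i in range(dataset.n_spectra)
        ])
        dataset = SpectralDataset(rows, dataset.axis, dataset.meta,
                                  stage="normalized")
        note("normalized pre-baselined input")
    save_dataset(dataset, outdir / "preprocessed.csv", outdir / "metadata.csv",
                 header=f"ramanmf {__version__} config={tag}")

    # --- factorization -----------------------------------------------------
    mc = config.model
    model = fit_gbrnmf(dataset, library, n_free=mc.n_free,
                       max_iter=mc.max_iter, tol=mc.tol, seed=mc.seed)
    scores = score_table(model, dataset)
    note(f"fit: k={len(model.factor_names_)} iter={model.n_iter_} "
         f"converged={model.converged_} "
         f"objective={model.objective_trace_[-1]:.6g}")
    np.savez(outdir / "model.npz", W=model.W_, A=model.A_, S=model.S_,
             degenerate=model.degenerate_,
             objective_trace=model.objective_trace_)
    with open(outdir / "model.json", "w") as fh:
        json.dump({
            "factor_names": model.factor_names_,
            "n_fixed": model.n_fixed_,
            "n_free": mc.n_free, "max_iter": mc.max_iter, "tol": mc.tol,
            "seed": mc.seed, "converged": bool(model.converged_),
            "iterations": int(model.n_iter_),
            "config_hash": tag, "version": __version__,
        }, fh, indent=2, sort_keys=True)
    _write_csv(scores.to_frame(), outdir / "scores.csv", tag)

    # --- analysis ----------------------------------------------------------
    ac = config.analysis
    pca = run_pca(dataset, n_components=ac.n_components)
    loadings = pd.DataFrame(
        pca.loadings, columns=[_FLOAT_FMT % w for w in dataset.axis.values])
    loadings.insert(0, "component",
                    [f"PC{i + 1}" for i in range(pca.n_components)])
    _write_csv(loadings, outdir / "pca_loadings.csv", tag)
    matches = pd.DataFrame([
        {"component": f"PC{i + 1}", "rank": r + 1, "chemical": name,
         "abs_pearson_r": sim}
        for i in range(pca.n_components)
        for r, (name, sim) in enumerate(
            match_loading_to_basis(pca.loadings[i], library)[:5])
    ])
    _write_csv(matches, outdir / "pca_basis_matches.csv", tag)

    summary = score_summary(scores, factors=ac.summary_factors)
    _write_csv(summary, outdir / "score_summary.csv", tag)

    corr_rows = []
    for fa, fb in ac.correlation_pairs:
        if fa not in scores.factor_names or fb not in scores.factor_names:
            continue
        subsets = ([{"cell_line": ln} for ln in
                    scores.meta["cell_line"].unique()]
                   if ac.correlate_by_line else [None])
        for sub in subsets:
            res = correlate_scores(scores, fa, fb, subset=sub)
            corr_rows.append({
                "factor_a": res.factor_a, "factor_b": res.factor_b,
                "subset": res.subset, "r": res.r, "p_value": res.p_value,
                "n": res.n,
            })
    if corr_rows:
        _write_csv(pd.DataFrame(corr_rows), outdir / "correlations.csv", tag)

    for factor in ac.control_factors:
        tests = compare_to_control(scores, factor, alpha=ac.alpha)
        _write_csv(tests, outdir / f"control_tests_{factor}.csv", tag)

    # --- classification ----------------------------------------------------
    cc = config.classify
    report = classification_report(
        scores, scores.meta, mapping=cc.mapping, n_trees=cc.n_trees,
        mtry=cc.mtry, split_fraction=cc.split_fraction, n_models=cc.n_models,
        n_permutation_repeats=cc.n_permutation_repeats, seed=cc.seed)
    _write_csv(report.importance, outdir / "importance.csv", tag)
    with open(outdir / "rf_report.json", "w") as fh:
        payload = report.to_json_dict()
        payload["config_hash"] = tag
        payload["version"] = __version__
        json.dump(payload, fh, indent=2, sort_keys=True)
    note(f"classified: oob_error={report.oob_error_pct:.3g}% "
         f"accuracy={report.metrics['radiosensitive']['accuracy_pct']:.4g}%"
         if 'radiosensitive' in report.metrics else "classified")

    # --- provenance --------------------------------------------------------
    with open(outdir / "provenance.json", "w") as fh:
        json.dump({
            "version": __version__, "config_hash": tag,
            "config": config.model_dump(mode="json"),
            "n_spectra": dataset.n_spectra,
            "log": log,
        }, fh, indent=2, sort_keys=True)
    (outdir / "run.log").write_text("\n".join(log) + "\n")

    return {
        "dataset": dataset, "library": library, "truth": truth,
        "model": model, "scores": scores, "pca": pca, "summary": summary,
        "report": report, "config_hash": tag,
    }
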