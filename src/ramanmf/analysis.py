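"""Score analytics: PCA validation and group statistics.

PCA is the unsupervised reference point the constrained factorization is
validated against: on data dominated by a single chemical's variation,
the first principal-component loading should resemble that chemical's
pure spectrum, which :func:`match_loading_to_basis` quantifies by
absolute Pearson correlation (PCA loadings are sign-ambiguous, and
published loading overlays are routinely inverted for display).

Group statistics follow the study layout: mean score +/- one standard
error per (cell line, dose, day) group, Pearson correlation between two
factors' scores on a metadata subset (e.g. the glucose-glycogen
association within a cell line), and per-group Welch tests against the
same-day unirradiated control of the same line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import (
    ConstantScoreError,
    MissingControlError,
    RamanMFError,
)
from .gbrnmf import ScoreTable
from .spectra import BasisLibrary, SpectralDataset

DEFAULT_GROUPING = ("cell_line", "dose_gy", "day")


@dataclass
class PCAResult:
    """Centered PCA of a spectral matrix.

    ``loadings`` rows are unit-norm principal axes with a deterministic
    sign convention: the largest-magnitude element of each loading is
    positive.  ``scores`` are the centered data projected onto them.
    """

    loadings: np.ndarray
    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    mean_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def run_pca(data, n_components: int = 2) -> PCAResult:
    """Column-mean-centered PCA by SVD with a fixed sign convention."""
    X = data.X if isinstance(data, SpectralDataset) else np.asarray(data, float)
    n, p = X.shape
    if n_components > min(n, p):
        raise RamanMFError(
            f"n_components={n_components} exceeds min(n, p)={min(n, p)}"
        )
    if n <= n_components:
        raise RamanMFError("need more spectra than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign: largest-|element| of each loading positive
    flip = np.sign(loadings[np.arange(n_components),
                            np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    return PCAResult(loadings, scores, pca.explained_variance_ratio_.copy(),
                     pca.mean_.copy())


def match_loading_to_basis(loading: np.ndarray,
                           library: BasisLibrary) -> list[tuple[str, float]]:
    """Rank library chemicals by |Pearson r| against a PC loading.

    Sign-invariant, so an inverted loading matches equally well.
    """
    loading = np.asarray(loading, dtype=float)
    if loading.shape != (library.B.shape[1],):
        raise RamanMFError(
            f"loading length {loading.size} != library axis length "
            f"{library.B.shape[1]}"
        )
    sims = [(name, float(abs(np.corrcoef(loading, row)[0, 1])))
            for name, row in zip(library.names, library.B)]
    return sorted(sims, key=lambda t: -t[1])


def score_summary(scores: ScoreTable, factors=None,
                  grouping=DEFAULT_GROUPING) -> pd.DataFrame:
    """Mean score, standard error and n per metadata group and factor.

    SE is the sample standard deviation over sqrt(n); singleton groups
    cannot carry an error bar and are flagged instead of reporting 0.
    """
    factors = list(factors) if factors is not None else list(scores.factor_names)
    unknown = [f for f in factors if f not in scores.factor_names]
    if unknown:
        raise RamanMFError(f"unknown factor names: {unknown}")
    frame = scores.to_frame()
    grouping = list(grouping)
    if frame.empty:
        raise RamanMFError("score table is empty")
    rows = []
    for key, grp in frame.groupby(grouping, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for f in factors:
            vals = grp[f].to_numpy()
            n = vals.size
            rows.append({
                **dict(zip(grouping, key)),
                "factor": f,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": n,
                "flag": "" if n > 1 else "singleton_group",
            })
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    factor_a: str
    factor_b: str
    subset: str
    r: float
    p_value: float
    n: int


def correlate_scores(scores: ScoreTable, factor_a: str, factor_b: str,
                     subset: dict | None = None) -> CorrelationResult:
    """Pearson correlation between two factors' scores on a metadata subset.

    ``subset`` maps metadata columns to required values, e.g.
    ``{"cell_line": "MCF7"}``.
    """
    frame = scores.to_frame()
    desc = "all"
    if subset:
        mask = np.ones(len(frame), dtype=bool)
        for col, val in subset.items():
            if col not in frame.columns:
                raise RamanMFError(f"unknown metadata column {col!r}")
            mask &= (frame[col] == val).to_numpy()
        frame = frame[mask]
        desc = ",".join(f"{k}={v}" for k, v in subset.items())
    n = len(frame)
    if n < 3:
        raise RamanMFError(f"subset {desc!r} has n={n} < 3")
    a = frame[factor_a].to_numpy() if factor_a in frame.columns else None
    b = frame[factor_b].to_numpy() if factor_b in frame.columns else None
    if a is None or b is None:
        raise RamanMFError(f"unknown factor {factor_a!r} or {factor_b!r}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ConstantScoreError(
            f"constant score column in subset {desc!r}; correlation undefined"
        )
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(factor_a, factor_b, desc, float(r), float(p), n)


def compare_to_control(scores: ScoreTable, factor: str, alpha: float = 0.05,
                       test: str = "welch", fdr: bool = False,
                       control_dose: float = 0.0) -> pd.DataFrame:
    """Test every dosed group against its same-day unirradiated control.

    For each (cell_line, day), each dose > 0 group is compared with the
    0 Gy group of the same line and day using Welch's two-sample t-test
    (or Mann-Whitney with ``test="mannwhitney"``).  No multiplicity
    correction by default; ``fdr=True`` applies Benjamini-Hochberg.
    """
    if factor not in scores.factor_names:
        raise RamanMFError(f"unknown factor {factor!r}")
    frame = scores.to_frame()
    rows = []
    for (line, day), grp in frame.groupby(["cell_line", "day"], sort=True):
        control = grp.loc[grp["dose_gy"] == control_dose, factor].to_numpy()
        doses = sorted(d for d in grp["dose_gy"].unique() if d != control_dose)
        if control.size == 0:
            if doses:
                raise MissingControlError(
                    f"no {control_dose:g} Gy control for cell_line={line}, "
                    f"day={day}"
                )
            continue
        for dose in doses:
            sample = grp.loc[grp["dose_gy"] == dose, factor].to_numpy()
            if test == "welch":
                stat, p = stats.ttest_ind(sample, control, equal_var=False)
            elif test == "mannwhitney":
                stat, p = stats.mannwhitneyu(sample, control,
                                             alternative="two-sided")
            else:
                raise RamanMFError(f"unknown test {test!r}")
            rows.append({
                "cell_line": line, "dose_gy": dose, "day": day,
                "factor": factor, "statistic": float(stat),
                "p_value": float(p), "n": int(sample.size),
                "n_control": int(control.size),
            })
    result = pd.DataFrame(rows)
    if result.empty:
        raise RamanMFError("no dosed groups to compare")
    if fdr:
        rejected, p_adj, _, _ = multipletests(result["p_value"], alpha=alpha,
                                              method="fdr_bh")
        result["p_adjusted"] = p_adj
        result["significant"] = rejected
    else:
        result["significant"] = result["p_value"] < alpha
    return result
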