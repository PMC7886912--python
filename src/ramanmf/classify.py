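"""Radio-sensitivity classification on factor scores.

A random forest (200 trees, 5 variables tried per split) is trained on
the per-cell factor scores to separate radio-sensitive from
radio-resistant cell lines, after a stratified 75/25 train/test split.
Variable importance is mean decrease in accuracy (MDA): the drop in
held-out accuracy when one score column is randomly permuted, averaged
over independently seeded split+fit repeats (10 by default).  The
out-of-bag (OOB) error of forests spanning a grid of tree counts and
per-split variable counts maps the hyperparameter sensitivity.

The three cell lines of the study ship as the default class mapping:
H460 (lung) and MCF7 (breast) are radio-resistant, LNCaP (prostate) is
radio-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .errors import RamanMFError, UnmappedCellLineError
from .gbrnmf import ScoreTable

RADIOSENSITIVE = "radiosensitive"
RADIORESISTANT = "radioresistant"
CLASS_ORDER = (RADIOSENSITIVE, RADIORESISTANT)

DEFAULT_CLASS_MAPPING = {
    "H460": RADIORESISTANT,
    "MCF7": RADIORESISTANT,
    "LNCaP": RADIOSENSITIVE,
}


def assign_radio_class(meta: pd.DataFrame,
                       mapping: dict | None = None) -> np.ndarray:
    """Map each spectrum's cell line to its radio-sensitivity class."""
    mapping = mapping if mapping is not None else DEFAULT_CLASS_MAPPING
    lines = meta["cell_line"]
    unmapped = sorted(set(lines.unique()) - set(mapping))
    if unmapped:
        raise UnmappedCellLineError(
            f"no radio-sensitivity mapping for cell line(s): {unmapped}"
        )
    return lines.map(mapping).to_numpy()


def split_train_test(n_or_scores, labels, fraction: float = 0.75,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified random split; returns (train_index, test_index).

    The two index sets partition ``range(n)`` exactly and preserve the
    class proportions to within one observation per class.  Identical
    seeds yield identical splits.
    """
    if not 0.0 < fraction < 1.0:
        raise RamanMFError(f"split fraction must be in (0, 1), got {fraction}")
    n = (n_or_scores.scores.shape[0] if isinstance(n_or_scores, ScoreTable)
         else int(n_or_scores))
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise RamanMFError(f"{labels.shape[0]} labels for {n} rows")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2].tolist()
        raise RamanMFError(f"class(es) with < 2 members cannot be split: {small}")
    train_idx, test_idx = train_test_split(
        np.arange(n), train_size=fraction, stratify=labels, random_state=seed,
    )
    return np.sort(train_idx), np.sort(test_idx)


def train_random_forest(X, y, n_trees: int = 200, mtry: int = 5,
                        seed: int = 0) -> RandomForestClassifier:
    """Fit a random forest with the study's settings and OOB tracking."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise RamanMFError("training labels contain a single class")
    if mtry > X.shape[1]:
        raise RamanMFError(
            f"mtry={mtry} exceeds the {X.shape[1]} available variables"
        )
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features=mtry, oob_score=True,
        random_state=seed, n_jobs=1,
    )
    clf.fit(X, y)
    return clf


# ---------------------------------------------------------------------------
# confusion matrix and derived metrics
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """2x2 counts; rows = observed class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, str] = CLASS_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise RamanMFError(f"confusion matrix must be 2x2, got {self.counts.shape}")
        if np.any(self.counts < 0) or self.counts.sum() == 0:
            raise RamanMFError("confusion counts must be >= 0 with total > 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts,
                            index=[f"observed_{c}" for c in self.labels],
                            columns=[f"predicted_{c}" for c in self.labels])


def evaluate_classifier(clf, X_test, y_test,
                        labels: tuple[str, str] = CLASS_ORDER) -> ConfusionMatrix:
    """Observed-vs-predicted counts on the held-out set."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise RamanMFError("test set is empty")
    known = set(clf.classes_)
    unseen = sorted(set(y_test) - known)
    if unseen:
        raise RamanMFError(f"test labels unseen in training: {unseen}")
    if set(labels) != known:
        raise RamanMFError(
            f"declared label order {labels} does not match training classes "
            f"{sorted(known)}"
        )
    pred = clf.predict(X_test)
    counts = np.zeros((2, 2), dtype=int)
    for i, obs in enumerate(labels):
        for j, prd in enumerate(labels):
            counts[i, j] = int(np.sum((y_test == obs) & (pred == prd)))
    return ConfusionMatrix(counts, tuple(labels))


def confusion_metrics(cm: ConfusionMatrix,
                      positive: str = RADIOSENSITIVE) -> dict:
    """Accuracy, sensitivity, specificity and false-positive share (all %).

    ``sensitivity = TP / (TP + FN)`` on the positive class,
    ``specificity = TN / (TN + FP)`` on the other, and the
    false-positive share is FP as a percentage of the whole test set.
    Undefined ratios (empty margins) are reported as None rather than
    NaN.  Values are full precision; round to one decimal for display.
    """
    if positive not in cm.labels:
        raise RamanMFError(f"positive class {positive!r} not in {cm.labels}")
    i = cm.labels.index(positive)
    j = 1 - i
    tp = cm.counts[i, i]
    fn = cm.counts[i, j]
    fp = cm.counts[j, i]
    tn = cm.counts[j, j]
    total = cm.total

    def pct(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "positive_class": positive,
        "accuracy_pct": pct(tp + tn, total),
        "sensitivity_pct": pct(tp, tp + fn),
        "specificity_pct": pct(tn, tn + fp),
        "precision_pct": pct(tp, tp + fp),
        "false_positive_pct_of_total": pct(fp, total),
        "n_total": total,
    }


# ---------------------------------------------------------------------------
# permutation importance (mean decrease accuracy)
# ---------------------------------------------------------------------------


def permutation_mda(clf, X_test, y_test, n_repeats: int = 10,
                    seed: int = 0) -> np.ndarray:
    """Held-out MDA of every variable for one fitted forest.

    For each variable the test column is permuted ``n_repeats`` times and
    the drop from the unpermuted accuracy is averaged.  All permuted
    copies of one variable are scored in a single batched predict call.
    Returned as accuracy fractions (0.01 = one percentage point).
    """
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    n, p = X_test.shape
    if p < 1:
        raise RamanMFError("need at least one variable")
    rng = np.random.default_rng(seed)
    base = float(np.mean(clf.predict(X_test) == y_test))
    mda = np.empty(p)
    for j in range(p):
        block = np.tile(X_test, (n_repeats, 1))
        for r in range(n_repeats):
            block[r * n:(r + 1) * n, j] = rng.permutation(X_test[:, j])
        pred = clf.predict(block)
        acc = np.mean(pred.reshape(n_repeats, n) == y_test[None, :], axis=1)
        mda[j] = base - float(acc.mean())
    return mda


def mda_importance(scores, labels, n_models: int = 10,
                   split_fraction: float = 0.75, n_trees: int = 200,
                   mtry: int = 5, n_permutation_repeats: int = 10,
                   seed: int = 0) -> pd.DataFrame:
    """MDA mean and SD over repeated stratified split + fit cycles.

    Model ``i`` uses seed ``seed + i`` for its split, forest and
    permutations (the seed ladder is recorded by callers for reruns).
    Returns one row per score column, including any unconstrained factor.
    """
    if n_models < 1:
        raise RamanMFError("n_models must be >= 1")
    if isinstance(scores, ScoreTable):
        X, names = scores.scores, list(scores.factor_names)
    else:
        X = np.asarray(scores, dtype=float)
        names = [f"var_{j + 1}" for j in range(X.shape[1])]
    labels = np.asarray(labels)
    per_model = np.empty((n_models, X.shape[1]))
    for i in range(n_models):
        s = seed + i
        tr, te = split_train_test(X.shape[0], labels, fraction=split_fraction,
                                  seed=s)
        clf = train_random_forest(X[tr], labels[tr], n_trees=n_trees,
                                  mtry=mtry, seed=s)
        per_model[i] = permutation_mda(clf, X[te], labels[te],
                                       n_repeats=n_permutation_repeats, seed=s)
    return pd.DataFrame({
        "variable": names,
        "mda_mean": per_model.mean(axis=0),
        "mda_sd": per_model.std(axis=0, ddof=1) if n_models > 1
        else np.zeros(X.shape[1]),
    })


def impurity_importance(clf, names=None) -> pd.DataFrame:
    """Mean decrease in node impurity (secondary importance measure)."""
    imp = clf.feature_importances_
    if names is None:
        names = [f"var_{j + 1}" for j in range(imp.size)]
    return pd.DataFrame({"variable": list(names), "impurity_importance": imp})


# ---------------------------------------------------------------------------
# OOB hyperparameter grid
# ---------------------------------------------------------------------------


@dataclass
class OOBGrid:
    """OOB error (%) per (n_trees, mtry) cell, averaged over repeats."""

    errors_pct: pd.DataFrame   # index = n_trees, columns = mtry
    n_reps: int


def oob_hyperparameter_grid(X, y, trees_range=range(100, 2001, 100),
                            mtry_range=range(1, 31), n_reps: int = 5,
                            seed: int = 0) -> OOBGrid:
    """Average OOB error over a grid of forest hyperparameters.

    Defaults span 100-2000 trees in steps of 100 and 1-30 variables per
    split, each cell averaged over ``n_reps`` seeded fits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    trees = list(trees_range)
    mtrys = list(mtry_range)
    if not trees or not mtrys:
        raise RamanMFError("hyperparameter ranges must be non-empty")
    if max(mtrys) > X.shape[1]:
        raise RamanMFError(
            f"mtry up to {max(mtrys)} exceeds the {X.shape[1]} variables"
        )
    grid = np.empty((len(trees), len(mtrys)))
    for a, n_trees in enumerate(trees):
        for b, mtry in enumerate(mtrys):
            errs = []
            for r in range(n_reps):
                clf = train_random_forest(X, y, n_trees=n_trees, mtry=mtry,
                                          seed=seed + r)
                errs.append(100.0 * (1.0 - clf.oob_score_))
            grid[a, b] = float(np.mean(errs))
    frame = pd.DataFrame(grid, index=pd.Index(trees, name="n_trees"),
                         columns=pd.Index(mtrys, name="mtry"))
    return OOBGrid(frame, n_reps)


# ---------------------------------------------------------------------------
# estimator wrapper and end-to-end report
# ---------------------------------------------------------------------------


class RadiosensitivityForest(ClassifierMixin, BaseEstimator):
    """Scikit-learn classifier wrapper with the study's forest settings.

    Thin wrapper over :class:`RandomForestClassifier` fixing the
    defaults (200 trees, 5 variables per split, OOB tracking) and adding
    the held-out MDA computation.
    """

    def __init__(self, n_trees: int = 200, mtry: int = 5, seed: int = 0):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed

    def fit(self, X, y):
        self.forest_ = train_random_forest(X, y, n_trees=self.n_trees,
                                           mtry=self.mtry, seed=self.seed)
        self.classes_ = self.forest_.classes_
        self.oob_error_pct_ = 100.0 * (1.0 - self.forest_.oob_score_)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def predict(self, X):
        return self.forest_.predict(X)

    def predict_proba(self, X):
        return self.forest_.predict_proba(X)

    def mda(self, X_test, y_test, n_repeats: int = 10) -> np.ndarray:
        return permutation_mda(self.forest_, X_test, y_test,
                               n_repeats=n_repeats, seed=self.seed)


@dataclass
class RFReport:
    """Bundle of one classification run: settings, confusion, metrics, MDA."""

    settings: dict
    confusion: ConfusionMatrix
    metrics: dict                # keyed by positive-class orientation
    importance: pd.DataFrame
    oob_error_pct: float
    impurity: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        return {
            "settings": self.settings,
            "confusion": {
                "labels": list(self.confusion.labels),
                "counts": self.confusion.counts.tolist(),
            },
            "metrics": self.metrics,
            "oob_error_pct": self.oob_error_pct,
        }


def classification_report(scores, meta_or_labels, mapping: dict | None = None,
                          n_trees: int = 200, mtry: int = 5,
                          split_fraction: float = 0.75, n_models: int = 10,
                          n_permutation_repeats: int = 10,
                          seed: int = 0,
                          include_impurity: bool = False) -> RFReport:
    """End-to-end run: label, split, fit, evaluate, MDA over repeats.

    Metrics are reported for both positive-class orientations, since
    sensitivity/specificity depend on which class is declared positive.
    """
    if isinstance(scores, ScoreTable):
        X, names = scores.scores, list(scores.factor_names)
    else:
        X = np.asarray(scores, dtype=float)
        names = [f"var_{j + 1}" for j in range(X.shape[1])]
    if isinstance(meta_or_labels, pd.DataFrame):
        labels = assign_radio_class(meta_or_labels, mapping)
    else:
        labels = np.asarray(meta_or_labels)
    tr, te = split_train_test(X.shape[0], labels, fraction=split_fraction,
                              seed=seed)
    clf = train_random_forest(X[tr], labels[tr], n_trees=n_trees, mtry=mtry,
                              seed=seed)
    cm = evaluate_classifier(clf, X[te], labels[te])
    metrics = {pos: confusion_metrics(cm, positive=pos) for pos in cm.labels}
    if isinstance(scores, ScoreTable):
        importance = mda_importance(scores, labels, n_models=n_models,
                                    split_fraction=split_fraction,
                                    n_trees=n_trees, mtry=mtry,
                                    n_permutation_repeats=n_permutation_repeats,
                                    seed=seed)
    else:
        importance = mda_importance(X, labels, n_models=n_models,
                                    split_fraction=split_fraction,
                                    n_trees=n_trees, mtry=mtry,
                                    n_permutation_repeats=n_permutation_repeats,
                                    seed=seed)
    report = RFReport(
        settings={
            "n_trees": n_trees, "mtry": mtry,
            "split_fraction": split_fraction, "n_models": n_models,
            "n_permutation_repeats": n_permutation_repeats,
            "seed": seed, "seed_ladder": [seed + i for i in range(n_models)],
        },
        confusion=cm,
        metrics=metrics,
        importance=importance,
        oob_error_pct=100.0 * (1.0 - clf.oob_score_),
        impurity=impurity_importance(clf, names) if include_impurity else None,
    )
    return report
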