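"""Basis-restricted non-negative matrix factorization.

The model decomposes a matrix of preprocessed spectra ``X`` (n x p) as

    X  ~=  W A S

with ``S`` (k x p) a non-negative basis matrix whose first ``m`` rows are
*fixed* to a library of reference chemical spectra and whose remaining
``n_free`` rows are estimated from the data; ``W`` (n x k) the
non-negative scores; and ``A`` a positive diagonal that absorbs
per-factor scale so that every non-degenerate column of ``W`` has mean
exactly 1.  ``A`` is a pure reparameterization: ``W A S`` equals the
unscaled fit bit-for-bit up to floating point.

The optimizer is block-coordinate alternating non-negative least
squares: each W row and each free basis column is an exactly solved NNLS
subproblem, so the squared Frobenius objective is non-increasing at
every iteration with no step-size tuning.  Each NNLS subproblem is
reduced through the Cholesky factor of the basis Gram matrix, making the
per-row solves independent of the number of wavenumbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cholesky, solve_triangular
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import AxisMismatchError, RamanMFError
from .spectra import BasisLibrary, SpectralDataset


# ---------------------------------------------------------------------------
# NNLS building blocks
# ---------------------------------------------------------------------------


def update_scores_nnls(X: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Row-wise non-negative least squares of ``X`` against ``basis``.

    Each output row ``w_i`` minimizes ``||x_i - w_i @ basis||^2`` subject
    to ``w_i >= 0``.  The (k x k) Gram reduction makes each solve cheap:
    with ``G = basis basis^T = R^T R`` the problem is equivalent to
    ``min ||R w - R^{-T} basis x||`` and is handed to an active-set NNLS.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    if X.shape[1] != basis.shape[1]:
        raise AxisMismatchError(
            f"X has {X.shape[1]} wavenumbers, basis has {basis.shape[1]}"
        )
    n, k = X.shape[0], basis.shape[0]
    row_norms = np.linalg.norm(basis, axis=1)
    if np.all(row_norms == 0):
        raise RamanMFError("basis rows are all zero")
    active = row_norms > 0
    sub = basis[active]
    G = sub @ sub.T
    W = np.zeros((n, k))
    rhs = sub @ X.T  # (k_active, n)
    try:
        R = cholesky(G, lower=False)
        Z = solve_triangular(R, rhs, trans="T", lower=False)
        for i in range(n):
            W[i, active], _ = nnls(R, Z[:, i])
    except LinAlgError:
        # collinear basis rows: fall back to the full-size problem
        At = sub.T
        for i in range(n):
            W[i, active], _ = nnls(At, X[i])
    return W


def update_free_bases(X: np.ndarray, W: np.ndarray, S: np.ndarray,
                      fixed_mask: np.ndarray) -> np.ndarray:
    """Optimal non-negative update of the free rows of ``S`` given ``W``.

    Fixed rows are returned bit-unchanged.  The subproblem is the exact
    transpose of the score update: each wavenumber column of the free
    block solves an NNLS against the free score columns.
    """
    fixed_mask = np.asarray(fixed_mask, dtype=bool)
    free = ~fixed_mask
    if not free.any():
        raise RamanMFError("no free basis rows to update")
    S_new = S.copy()
    residual = X - W[:, fixed_mask] @ S[fixed_mask]
    W_free = W[:, free]
    if not np.any(W_free):
        S_new[free] = 0.0  # degenerate: no mass on the free factors
        return S_new
    S_new[free] = update_scores_nnls(residual.T, W_free.T).T
    return S_new


def normalize_factor_scale(W_raw: np.ndarray):
    """Extract the diagonal ``A`` so each score column has mean 1.

    Returns ``(W, A, degenerate)`` with ``W * A == W_raw`` exactly.
    All-zero columns are flagged degenerate and passed through with
    ``A = 1`` so the column count is stable.
    """
    W_raw = np.atleast_2d(np.asarray(W_raw, dtype=float))
    A = W_raw.mean(axis=0)
    degenerate = A <= 0
    A = np.where(degenerate, 1.0, A)
    return W_raw / A, A, degenerate


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class GBRNMF(TransformerMixin, BaseEstimator):
    """Basis-restricted NMF estimator (scikit-learn API).

    Parameters
    ----------
    library : BasisLibrary or ndarray (m, p)
        Reference chemical spectra fixed as the first ``m`` rows of S.
    n_free : int, default 1
        Number of unconstrained basis rows estimated from the data, as
        in the 30-chemicals-plus-one-unconstrained-factor configuration.
    max_iter : int, default 500
    tol : float, default 1e-8
        Relative change of the objective below which iteration stops.
    seed : int, default 0
        Recorded for provenance; the default initialization (scores by
        NNLS against the fixed library, free rows from the non-negative
        part of the leading residual singular vector) is deterministic.

    Attributes
    ----------
    W_ : ndarray (n, k)       normalized scores, column means 1
    A_ : ndarray (k,)         positive diagonal scaling
    S_ : ndarray (k, p)       basis matrix; first ``n_fixed_`` rows are
                              bit-identical to the input library
    factor_names_ : list of str
    n_fixed_ : int
    objective_trace_ : ndarray  squared Frobenius error per iteration
    converged_ : bool
    n_iter_ : int
    degenerate_ : ndarray (k,) bool flags for all-zero factors
    """

    def __init__(self, library=None, n_free: int = 1, max_iter: int = 500,
                 tol: float = 1e-8, seed: int = 0):
        self.library = library
        self.n_free = n_free
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    # -- helpers ------------------------------------------------------------

    def _basis_matrix(self):
        if self.library is None:
            raise RamanMFError("GBRNMF requires a basis library")
        if isinstance(self.library, BasisLibrary):
            return self.library.B, list(self.library.names)
        B = np.atleast_2d(np.asarray(self.library, dtype=float))
        return B, [f"basis_{j + 1}" for j in range(B.shape[0])]

    @staticmethod
    def _init_free_rows(residual: np.ndarray, n_free: int) -> np.ndarray:
        """Non-negative parts of the leading residual singular vectors."""
        p = residual.shape[1]
        rows = np.zeros((n_free, p))
        if not np.any(residual):
            return rows
        _, _, vt = np.linalg.svd(residual, full_matrices=False)
        for j in range(min(n_free, vt.shape[0])):
            v = vt[j]
            pos, neg = np.clip(v, 0, None), np.clip(-v, 0, None)
            row = pos if np.linalg.norm(pos) >= np.linalg.norm(neg) else neg
            total = row.sum()
            rows[j] = row / total if total > 0 else 0.0
        return rows

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y=None):
        if isinstance(X, SpectralDataset):
            X = X.X
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.size == 0:
            raise RamanMFError("cannot fit on empty data")
        if np.any(X < 0):
            raise RamanMFError("X must be non-negative (preprocess first)")
        B, names = self._basis_matrix()
        if B.shape[1] != X.shape[1]:
            raise AxisMismatchError(
                f"library has {B.shape[1]} wavenumbers, data has {X.shape[1]}"
            )
        n_free = int(self.n_free)
        if n_free < 0:
            raise ValueError("n_free must be >= 0")
        m = B.shape[0]
        k = m + n_free

        W = update_scores_nnls(X, B)
        if n_free > 0:
            free0 = self._init_free_rows(X - W @ B, n_free)
            S = np.vstack([B, free0])
            W = np.hstack([W, np.zeros((X.shape[0], n_free))])
        else:
            S = B.copy()

        fixed_mask = np.zeros(k, dtype=bool)
        fixed_mask[:m] = True

        trace = []
        prev = np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            W = update_scores_nnls(X, S)
            if n_free > 0:
                S = update_free_bases(X, W, S, fixed_mask)
            obj = float(np.linalg.norm(X - W @ S) ** 2)
            trace.append(obj)
            if it > 1 and prev - obj <= self.tol * max(prev, np.finfo(float).tiny):
                converged = True
                break
            prev = obj

        # fixed rows were never written to; assert the contract anyway
        S[:m] = B

        W_norm, A, degenerate = normalize_factor_scale(W)
        self.W_, self.A_, self.S_ = W_norm, A, S
        self.factor_names_ = names + [f"unconstrained_{j + 1}" for j in range(n_free)]
        self.n_fixed_ = m
        self.objective_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.n_iter_ = len(trace)
        self.degenerate_ = degenerate
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Project spectra onto the fitted basis (normalized score scale)."""
        if isinstance(X, SpectralDataset):
            X = X.X
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.S_.shape[1]:
            raise AxisMismatchError(
                f"spectra have {X.shape[1]} wavenumbers, model has {self.S_.shape[1]}"
            )
        return update_scores_nnls(X, self.S_) / self.A_

    def inverse_transform(self, W):
        return np.asarray(W) * self.A_ @ self.S_

    def reconstruction_error(self, X) -> float:
        """Squared Frobenius norm of ``X - W A S`` for the training fit."""
        if isinstance(X, SpectralDataset):
            X = X.X
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape != (self.W_.shape[0], self.S_.shape[1]):
            raise AxisMismatchError(
                f"X shape {X.shape} does not match fitted model "
                f"({self.W_.shape[0]}, {self.S_.shape[1]})"
            )
        return float(np.linalg.norm(X - (self.W_ * self.A_) @ self.S_) ** 2)


# ---------------------------------------------------------------------------
# score tables and module-level wrappers
# ---------------------------------------------------------------------------


@dataclass
class ScoreTable:
    """Per-spectrum factor scores joined to experimental metadata."""

    scores: np.ndarray
    factor_names: list[str]
    meta: pd.DataFrame

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        self.factor_names = list(self.factor_names)
        if self.scores.shape[1] != len(self.factor_names):
            raise RamanMFError(
                f"{self.scores.shape[1]} score columns for "
                f"{len(self.factor_names)} factor names"
            )
        if len(self.meta) != self.scores.shape[0]:
            raise RamanMFError(
                f"metadata has {len(self.meta)} rows for "
                f"{self.scores.shape[0]} score rows"
            )
        if np.any(self.scores < 0):
            raise RamanMFError("scores must be non-negative")
        self.meta = self.meta.reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        frame = self.meta.copy()
        for j, name in enumerate(self.factor_names):
            frame[name] = self.scores[:, j]
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, factor_names) -> "ScoreTable":
        meta_cols = [c for c in frame.columns if c not in factor_names]
        return cls(frame[list(factor_names)].to_numpy(dtype=float),
                   list(factor_names), frame[meta_cols])

    def column(self, name: str) -> np.ndarray:
        return self.scores[:, self.factor_names.index(name)]


def fit_gbrnmf(data: SpectralDataset, library: BasisLibrary, n_free: int = 1,
               max_iter: int = 500, tol: float = 1e-8, seed: int = 0) -> GBRNMF:
    """Fit the factorization to a dataset, checking axis compatibility."""
    if library.axis != data.axis:
        raise AxisMismatchError("library and dataset wavenumber axes differ")
    model = GBRNMF(library=library, n_free=n_free, max_iter=max_iter,
                   tol=tol, seed=seed)
    model.fit(data.X)
    model.axis_ = data.axis
    return model


def score_table(model: GBRNMF, data: SpectralDataset) -> ScoreTable:
    """Training-score table of a fitted model (the normalized W)."""
    return ScoreTable(model.W_, model.factor_names_, data.meta)


def project_scores(model: GBRNMF, new_data: SpectralDataset) -> ScoreTable:
    """Score held-out spectra on a fitted basis, normalized scale."""
    axis = getattr(model, "axis_", None)
    if axis is not None and axis != new_data.axis:
        raise AxisMismatchError("new data is on a different wavenumber axis")
    return ScoreTable(model.transform(new_data.X), model.factor_names_, new_data.meta)


def reconstruction_error(model: GBRNMF, data: SpectralDataset) -> float:
    return model.reconstruction_error(data.X)
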