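"""Collaborative and sparse representation classifiers.

Both classifiers code a query sample y as a linear combination of *all*
training samples stacked as columns of a dictionary X = [X_1 ... X_K]
(contiguous class blocks), then assign the class whose sub-coefficients
reconstruct y best.

* CRC solves the ridge-coding problem
      rho_hat = argmin_a ||y - X a||^2 + lambda ||a||^2
  through the closed form rho_hat = P y with
      P = (X^T X + lambda I)^{-1} X^T,
  and decides with the regularized residuals
      r_i = ||y - X_i rho_hat_i|| / ||rho_hat_i||,
  so a class is favoured both for reconstructing y well and for absorbing a
  large share of the coding energy.  P does not depend on y and is computed
  once per training set.

* SRC codes y sparsely with orthogonal matching pursuit and decides with the
  plain residual e_i = ||y - X_i alpha_hat_i||.

Queries are unit-normalized like dictionary columns, which makes both
decisions invariant to positive rescaling of the query.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import linalg

from .data_io import LabeledExpressionSet
from .preprocess import normalize_columns, normalize_vector
from .projection import SparseProjection, apply_projection

logger = logging.getLogger(__name__)

__all__ = [
    "Dictionary",
    "CRCModel",
    "CodingVector",
    "ResidualReport",
    "build_dictionary",
    "fit_crc",
    "code_sample",
    "classify_crc",
    "solve_omp",
    "classify_src",
]


@dataclasses.dataclass
class Dictionary:
    """Column-sample training matrix partitioned into class blocks.

    ``X`` is m x n with unit-norm columns; ``class_slices[i]`` selects the
    contiguous columns of class ``class_names[i]``.
    """

    X: np.ndarray
    class_slices: list[slice]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if len(self.class_slices) != len(self.class_names):
            raise ValueError("one slice per class required")
        covered = sum(s.stop - s.start for s in self.class_slices)
        if covered != self.n_atoms:
            raise ValueError("class slices must partition the columns")
        for s in self.class_slices:
            if s.stop - s.start < 1:
                raise ValueError("every class needs at least one column")

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def build_dictionary(
    train: LabeledExpressionSet,
    projection: SparseProjection | None = None,
) -> Dictionary:
    """Project (optionally) and column-normalize training samples.

    Columns are regrouped contiguously by class following the first-appearance
    order of ``train.class_names``; within a class the original sample order
    is preserved.
    """
    if train.n_samples == 0:
        raise ValueError("empty training set")
    classes = train.class_names
    if len(classes) < 1:
        raise ValueError("training set has no classes")
    idx = train.label_indices()
    order = np.concatenate([np.nonzero(idx == k)[0] for k in range(len(classes))])
    X = train.values[:, order]
    if projection is not None:
        X = apply_projection(projection, X)
    X = normalize_columns(X)
    slices = []
    start = 0
    for k in range(len(classes)):
        cnt = int(np.sum(idx == k))
        if cnt == 0:
            raise ValueError(f"class {classes[k]!r} has no samples")
        slices.append(slice(start, start + cnt))
        start += cnt
    return Dictionary(X=X, class_slices=slices, class_names=list(classes))


@dataclasses.dataclass
class CRCModel:
    """Precomputed ridge-coding operator P = (X^T X + lambda I)^{-1} X^T."""

    P: np.ndarray
    lam: float
    dictionary: Dictionary


def fit_crc(dictionary: Dictionary, lam: float = 1e-3) -> CRCModel:
    """Compute the coding operator once for a given dictionary and ridge.

    ``P`` is obtained by solving the symmetric positive-definite system
    (X^T X + lambda I) Z = X^T with a Cholesky factorization rather than an
    explicit inverse; lambda > 0 guarantees positive definiteness even in
    the under-determined n > m regime that motivates the regularization.
    """
    if lam <= 0:
        raise ValueError(
            f"lambda must be > 0 (got {lam}); the unregularized least square "
            "is rank-deficient whenever there are more atoms than features"
        )
    X = dictionary.X
    G = X.T @ X + lam * np.eye(dictionary.n_atoms)
    c, low = linalg.cho_factor(G)
    P = linalg.cho_solve((c, low), X.T)
    return CRCModel(P=P, lam=float(lam), dictionary=dictionary)


@dataclasses.dataclass
class CodingVector:
    """Coefficients of a query over the dictionary, split by class block."""

    coefficients: np.ndarray
    by_class: list[np.ndarray]
    residual_vector: np.ndarray
    rank_deficient: bool = False


def _split(dictionary: Dictionary, coef: np.ndarray) -> list[np.ndarray]:
    return [coef[s] for s in dictionary.class_slices]


def code_sample(model: CRCModel, y: np.ndarray) -> CodingVector:
    """Code a (already projected/normalized) query: rho_hat = P y."""
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != model.dictionary.m:
        raise ValueError(
            f"query has {y.shape[0]} features, dictionary expects "
            f"{model.dictionary.m}"
        )
    coef = model.P @ y
    return CodingVector(
        coefficients=coef,
        by_class=_split(model.dictionary, coef),
        residual_vector=y - model.dictionary.X @ coef,
    )


@dataclasses.dataclass
class ResidualReport:
    """Per-class residuals and the argmin decision.

    Ties break to the lowest class index; a class whose coding sub-vector is
    exactly zero receives an infinite regularized residual.
    """

    per_class_residuals: np.ndarray
    predicted_class: str
    predicted_index: int
    coding: CodingVector | None = None


def _decide(residuals: np.ndarray, class_names: list[str],
            coding: CodingVector | None) -> ResidualReport:
    best = int(np.argmin(residuals))
    ties = np.nonzero(residuals == residuals[best])[0]
    if len(ties) > 1:
        logger.warning("residual tie among classes %s; picking lowest index",
                       [class_names[i] for i in ties])
    return ResidualReport(per_class_residuals=residuals,
                          predicted_class=class_names[best],
                          predicted_index=best, coding=coding)


def classify_crc(model: CRCModel, y: np.ndarray,
                 normalize_query: bool = True) -> ResidualReport:
    """Classify a query with the regularized residual rule.

    r_i = ||y - X_i rho_hat_i|| / ||rho_hat_i||; if every class has a zero
    sub-vector (so every r_i is infinite) the decision falls back to the
    unregularized residuals with a logged warning.
    """
    y = np.asarray(y, dtype=float).ravel()
    if normalize_query:
        y = normalize_vector(y)
    coding = code_sample(model, y)
    D = model.dictionary
    K = D.n_classes
    resid = np.empty(K)
    raw = np.empty(K)
    for i, s in enumerate(D.class_slices):
        part = coding.by_class[i]
        raw[i] = np.linalg.norm(y - D.X[:, s] @ part)
        norm_i = np.linalg.norm(part)
        resid[i] = raw[i] / norm_i if norm_i > 0 else np.inf
    if not np.isfinite(resid).any():
        logger.warning("all coding sub-vectors are zero; falling back to "
                       "unregularized residuals")
        resid = raw
    return _decide(resid, D.class_names, coding)


def classify_crc_batch(model: CRCModel, Y: np.ndarray,
                       normalize_query: bool = True) -> list[ResidualReport]:
    """Classify the columns of Y, reusing the stored operator P.

    Implemented as a per-column loop over the exact single-query path so
    that batch predictions are bit-identical to one-at-a-time calls.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != model.dictionary.m and Y.shape[1] == model.dictionary.m:
        Y = Y.T
    return [classify_crc(model, Y[:, j], normalize_query=normalize_query)
            for j in range(Y.shape[1])]


def solve_omp(X: np.ndarray, y: np.ndarray, max_nonzeros: int,
              residual_tol: float = 1e-10) -> CodingVector:
    """Greedy orthogonal matching pursuit over unit-norm columns.

    Repeatedly pick the column most correlated (in absolute value) with the
    current residual, re-fit least squares on the selected support, and stop
    once the residual norm drops to ``residual_tol`` or the support reaches
    ``max_nonzeros``.  If the support becomes numerically rank-deficient the
    last stable solution is returned with ``rank_deficient=True``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if max_nonzeros < 1:
        raise ValueError("max_nonzeros must be >= 1")
    n = X.shape[1]
    support: list[int] = []
    coef_s = np.zeros(0)
    resid = y.copy()
    rank_deficient = False
    while len(support) < min(max_nonzeros, n):
        if np.linalg.norm(resid) <= residual_tol:
            break
        corr = np.abs(X.T @ resid)
        corr[support] = -1.0  # never reselect
        j = int(np.argmax(corr))
        trial = support + [j]
        Xs = X[:, trial]
        sol, _, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
        if rank < len(trial):
            rank_deficient = True
            break
        support = trial
        coef_s = sol
        resid = y - Xs @ sol
    coef = np.zeros(n)
    if support:
        coef[support] = coef_s
    return CodingVector(coefficients=coef, by_class=[],
                        residual_vector=y - X @ coef,
                        rank_deficient=rank_deficient)


def classify_src(
    dictionary: Dictionary,
    y: np.ndarray,
    max_nonzeros: int | None = None,
    residual_tol: float = 1e-6,
    normalize_query: bool = True,
) -> ResidualReport:
    """Sparse-representation classification with an OMP coder.

    The query is coded over the full dictionary; the decision uses the plain
    per-class reconstruction error e_i = ||y - X_i alpha_hat_i|| (no
    coefficient-norm regularization), ties to the lowest class index.
    ``max_nonzeros`` defaults to min(m, n).
    """
    y = np.asarray(y, dtype=float).ravel()
    if normalize_query:
        y = normalize_vector(y)
    if max_nonzeros is None:
        max_nonzeros = min(dictionary.m, dictionary.n_atoms)
    coding = solve_omp(dictionary.X, y, max_nonzeros=max_nonzeros,
                       residual_tol=residual_tol)
    coding.by_class = _split(dictionary, coding.coefficients)
    K = dictionary.n_classes
    errs = np.empty(K)
    for i, s in enumerate(dictionary.class_slices):
        errs[i] = np.linalg.norm(y - dictionary.X[:, s] @ coding.by_class[i])
    return _decide(errs, dictionary.class_names, coding)
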