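"""Exhaustive best-subset logistic model search scored by cross-validated AIC.

Every amino-acid subset up to a size cap is fitted by unconditional
logistic regression; each candidate's score is an AIC computed from its
leave-one-out out-of-sample predicted probabilities (the Bernoulli deviance
of the held-out predictions plus the usual 2·(k+1) penalty), and the
minimum-AIC subset wins.  The cross-validated deviance without the penalty
is available as a variant, since either reading is defensible for a
criterion built from held-out function values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, inf

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.special import expit

from .errors import FitError, SearchError

__all__ = [
    "LogisticFit", "ModelCandidate", "fit_logistic", "loocv_probs",
    "cv_aic", "enumerate_subsets", "count_subsets", "exhaustive_search",
]

#: probabilities are clipped into [CLIP, 1-CLIP] before taking logs, so a
#: separated fold cannot produce an infinite deviance
CLIP = 1e-12


@dataclass
class LogisticFit:
    beta: np.ndarray       # intercept first, then one slope per column
    loglik: float
    converged: bool
    iterations: int


def _logistic_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # -log(1 + exp(-eta)) on cases, -log(1 + exp(eta)) on controls,
    # computed stably via logaddexp
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _newton_logistic(Xd: np.ndarray, y: np.ndarray, tol: float,
                     max_iter: int,
                     start: np.ndarray | None) -> LogisticFit:
    """Newton/IRLS core on a pre-built design (intercept included).

    No validation: callers check class balance and rank once.
    """
    beta = (np.zeros(Xd.shape[1]) if start is None
            else np.asarray(start, dtype=float).copy())
    eta = Xd @ beta
    ll = _logistic_loglik(eta, y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(eta)
        w = p * (1.0 - p)
        grad = Xd.T @ (y - p)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break                      # singular information: separation
        # step-halving if the likelihood does not improve
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _logistic_loglik(Xd @ cand, y)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta = cand
        eta = Xd @ beta
        ll = ll_new
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break
    return LogisticFit(beta=beta, loglik=ll, converged=converged,
                       iterations=it)


def fit_logistic(X, y, tol: float = 1e-8, max_iter: int = 100,
                 start: np.ndarray | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    ``X`` is the design of raw concentrations (no intercept column; one is
    prepended).  Convergence when the largest coefficient change is below
    ``tol``; non-convergence (e.g. complete separation) is reported via
    the ``converged`` flag rather than raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise FitError("y must be a 0/1 case indicator")
    if y.min() == y.max():
        raise FitError("y contains a single class")
    Xd = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise FitError("design matrix is rank deficient after adding the "
                       "intercept")
    return _newton_logistic(Xd, y, tol, max_iter, start)


def predict_proba(fit: LogisticFit, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = fit.beta[0] + X @ fit.beta[1:]
    return expit(eta)


def loocv_probs(X, y, tol: float = 1e-8,
                max_iter: int = 100) -> tuple[np.ndarray, bool]:
    """Leave-one-out out-of-sample predicted case probabilities.

    For each subject, the model is refitted on the other n-1 subjects
    (warm-started at the full-data solution) and the fitted logistic
    function is evaluated at the held-out subject: exactly n refits,
    deterministic.  Returns (probabilities, all_folds_converged); a fold
    whose refit does not converge poisons the candidate (the caller maps
    it to an infinite cross-validated AIC).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < k + 2:
        raise FitError(f"need at least {k + 2} subjects for a {k}-variable "
                       f"LOOCV, got {n}")
    full = fit_logistic(X, y, tol=tol, max_iter=max_iter)
    Xd = np.column_stack([np.ones(n), X])
    probs = np.empty(n)
    ok = full.converged
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        yi = y[mask]
        if yi.min() == yi.max():       # fold lost its only case/control
            ok = False
            mask[i] = True
            probs[i] = np.nan
            continue
        fit = _newton_logistic(Xd[mask], yi, tol, max_iter, full.beta)
        ok = ok and fit.converged
        probs[i] = expit(Xd[i] @ fit.beta)
        mask[i] = True
    return probs, ok


def cv_aic(cv_probs, y, subset_size: int) -> float:
    """AIC from out-of-fold probabilities.

    -2 x (Bernoulli log-likelihood of y under cv_probs) + 2 x (subset_size
    + 1); probabilities are clipped to [1e-12, 1 - 1e-12] first.
    """
    cv_probs = np.asarray(cv_probs, dtype=float)
    y = np.asarray(y, dtype=float)
    if cv_probs.shape != y.shape:
        raise ValueError(f"length mismatch: {cv_probs.shape} probabilities "
                         f"vs {y.shape} outcomes")
    p = np.clip(cv_probs, CLIP, 1.0 - CLIP)
    ll = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    return -2.0 * ll + 2.0 * (subset_size + 1)


def enumerate_subsets(p: int, k_max: int):
    """Yield every subset of {0..p-1} of size 1..k_max once, in
    (size, lexicographic) order."""
    if not 1 <= k_max <= p:
        raise ValueError(f"k_max must be in [1, {p}], got {k_max}")
    for k in range(1, k_max + 1):
        yield from itertools.combinations(range(p), k)


def count_subsets(p: int, k_max: int) -> int:
    if not 1 <= k_max <= p:
        raise ValueError(f"k_max must be in [1, {p}], got {k_max}")
    return sum(comb(p, k) for k in range(1, k_max + 1))


@dataclass
class ModelCandidate:
    """One evaluated amino-acid subset."""

    subset: tuple[str, ...]
    beta: np.ndarray | None          # full-data fit, intercept first
    cv_probs: np.ndarray | None      # out-of-fold case probabilities
    cv_aic: float                    # +inf when any fold fails
    converged: bool
    penalized: bool = field(default=True, repr=False)


def _evaluate_subset(idx: tuple[int, ...], X: np.ndarray, y: np.ndarray,
                     variables: tuple[str, ...],
                     penalty: bool) -> ModelCandidate:
    Xs = X[:, list(idx)]
    subset = tuple(variables[j] for j in idx)
    try:
        probs, ok = loocv_probs(Xs, y)
    except FitError:
        return ModelCandidate(subset, None, None, inf, False, penalty)
    if not ok:
        return ModelCandidate(subset, None, probs, inf, False, penalty)
    aic = cv_aic(probs, y, len(idx))
    if not penalty:                    # pure cross-validated deviance
        aic -= 2.0 * (len(idx) + 1)
    full = fit_logistic(Xs, y)
    return ModelCandidate(subset, full.beta, probs, aic, True, penalty)


def exhaustive_search(data: pd.DataFrame | np.ndarray, y=None,
                      variables: list[str] | None = None, k_max: int = 6,
                      workers: int = 1, penalty: bool = True,
                      ) -> list[ModelCandidate]:
    """Evaluate every subset of size 1..k_max and rank by cross-validated AIC.

    ``data`` is either a cohort DataFrame (with a ``group`` column and the
    candidate columns) or a numeric matrix with ``y`` and ``variables``
    supplied.  Candidates are sorted ascending by cv_aic, ties broken by
    smaller subset then lexicographic name order; non-convergent
    candidates rank last.  The ranking is independent of ``workers`` and
    of evaluation order.  With ``penalty=False`` the score is the pure
    cross-validated deviance (no 2·(k+1) term).
    """
    if isinstance(data, pd.DataFrame):
        if variables is None:
            from .synthetic_data import AMINO_ACIDS
            variables = [c for c in AMINO_ACIDS if c in data.columns]
        if y is None:
            y = (data["group"] == "case").astype(float).to_numpy()
        X = data.loc[:, list(variables)].to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if y is None or variables is None:
            raise ValueError("matrix input requires y and variables")
        y = np.asarray(y, dtype=float)
    variables = tuple(variables)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise SearchError("need at least 2 subjects per class")

    subsets = list(enumerate_subsets(len(variables), k_max))
    if workers > 1:
        chunks = np.array_split(np.arange(len(subsets)),
                                min(8 * workers, len(subsets)))
        results_nested = Parallel(n_jobs=workers)(
            delayed(lambda ids: [
                _evaluate_subset(subsets[i], X, y, variables, penalty)
                for i in ids])(chunk) for chunk in chunks)
        candidates = [c for chunk in results_nested for c in chunk]
    else:
        candidates = [_evaluate_subset(s, X, y, variables, penalty)
                      for s in subsets]
    candidates.sort(key=lambda c: (c.cv_aic, len(c.subset), c.subset))
    if not np.isfinite(candidates[0].cv_aic):
        raise SearchError("every candidate model failed to converge")
    return candidates
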