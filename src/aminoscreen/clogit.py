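"""Conditional logistic regression over 1:m matched strata.

The matched design is conditioned out rather than modelled: within each
stratum (one case plus its m matched controls) the conditional likelihood
of the case being the one observed case is

    P(case | stratum) = exp(x_case' b) / sum_j exp(x_j' b),

so stratum-specific intercepts — and with them the matching factors age,
gender and smoking — cancel.  The fitted linear predictor x' b is the
discriminant score (the logit of the conditional-logistic function value)
and is applied unchanged to matched subjects, unmatched test-set subjects
and external patient groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, SchemaError

__all__ = ["StratumData", "ConditionalFit", "conditional_loglik",
           "fit_conditional", "discriminant_score", "strata_from_matched"]


@dataclass
class StratumData:
    """Flattened stratified design, sorted by stratum.

    ``X`` stacks all member covariate rows; ``y`` marks the single case of
    each stratum; ``offsets`` gives each stratum's first row, so stratum s
    occupies rows offsets[s]:offsets[s+1].
    """

    X: np.ndarray          # N x k
    y: np.ndarray          # N, 0/1
    offsets: np.ndarray    # S+1
    variables: tuple[str, ...]

    @property
    def n_strata(self) -> int:
        return len(self.offsets) - 1

    @property
    def stratum_index(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_strata), np.diff(self.offsets))


def _as_stratum_data(strata, variables=None) -> StratumData:
    if isinstance(strata, StratumData):
        return strata
    # list of (X_s, case_index) pairs
    if not strata:
        raise ValueError("empty strata list")
    blocks, ys = [], []
    for Xs, case_idx in strata:
        Xs = np.atleast_2d(np.asarray(Xs, dtype=float))
        if Xs.shape[0] < 2:
            raise FitError("every stratum needs at least 2 members")
        blocks.append(Xs)
        y = np.zeros(Xs.shape[0])
        y[case_idx] = 1.0
        ys.append(y)
    sizes = [b.shape[0] for b in blocks]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    k = blocks[0].shape[1]
    names = tuple(variables) if variables else tuple(
        f"x{j}" for j in range(k))
    return StratumData(X=np.vstack(blocks), y=np.concatenate(ys),
                       offsets=offsets, variables=names)


def strata_from_matched(matched: pd.DataFrame,
                        variables: list[str]) -> StratumData:
    """Build the stratified design from a long matched table.

    ``matched`` needs ``stratum_id`` and ``group`` columns plus the
    selected amino-acid columns.
    """
    missing = [v for v in variables if v not in matched.columns]
    if missing:
        raise SchemaError(f"matched table is missing column(s): {missing}")
    df = matched.sort_values("stratum_id", kind="stable")
    ids = df["stratum_id"].to_numpy()
    X = df.loc[:, list(variables)].to_numpy(dtype=float)
    y = (df["group"] == "case").astype(float).to_numpy()
    boundaries = np.flatnonzero(np.diff(ids)) + 1
    offsets = np.concatenate([[0], boundaries, [len(ids)]])
    sd = StratumData(X=X, y=y, offsets=offsets, variables=tuple(variables))
    _validate(sd)
    return sd


def _validate(sd: StratumData) -> None:
    sizes = np.diff(sd.offsets)
    if (sizes < 2).any():
        raise FitError("every stratum needs at least 2 members")
    case_counts = np.add.reduceat(sd.y, sd.offsets[:-1])
    if not np.allclose(case_counts, 1.0):
        bad = np.flatnonzero(~np.isclose(case_counts, 1.0))
        raise FitError(f"strata {bad.tolist()[:5]} do not contain exactly "
                       f"one case")


def conditional_loglik(beta, strata, variables=None) -> float:
    """Conditional log-likelihood sum_s [x_case' b - log sum_j exp(x_j' b)].

    The within-stratum log-sum-exp is computed stably by max subtraction.
    """
    sd = _as_stratum_data(strata, variables)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = sd.X @ beta
    starts = sd.offsets[:-1]
    m = np.maximum.reduceat(eta, starts)
    idx = sd.stratum_index
    w = np.exp(eta - m[idx])
    denom = np.add.reduceat(w, starts)
    return float(np.sum(eta[sd.y == 1.0]) - np.sum(np.log(denom) + m))


@dataclass
class ConditionalFit:
    """Fitted conditional-logistic model (no intercept: conditioned out)."""

    variables: tuple[str, ...]
    beta: np.ndarray         # log-odds per μM
    se: np.ndarray           # from the inverse observed information
    wald_p: np.ndarray       # (beta/se)^2 against chi-square(1)
    loglik: float
    null_loglik: float       # at beta = 0
    converged: bool
    iterations: int
    n_strata: int

    def lr_pvalues(self, sd: StratumData) -> np.ndarray:
        """Likelihood-ratio p per variable: refit without that variable."""
        out = np.empty(len(self.variables))
        for j in range(len(self.variables)):
            keep = [i for i in range(len(self.variables)) if i != j]
            if keep:
                reduced = fit_conditional(StratumData(
                    X=sd.X[:, keep], y=sd.y, offsets=sd.offsets,
                    variables=tuple(self.variables[i] for i in keep)))
                ll0 = reduced.loglik
            else:
                ll0 = self.null_loglik
            out[j] = stats.chi2.sf(2.0 * (self.loglik - ll0), df=1)
        return out


def fit_conditional(strata, variables=None, tol: float = 1e-8,
                    max_iter: int = 100) -> ConditionalFit:
    """Newton-Raphson maximisation of the conditional log-likelihood.

    Convergence when the gradient norm falls below ``tol``; monotone
    step-halving guards against likelihood decreases; standard errors come
    from the inverse observed information at the optimum.  Non-convergence
    or a singular information matrix yields a flagged fit; a covariate
    constant within every stratum raises a no-information
    :class:`~aminoscreen.errors.FitError` naming it.
    """
    sd = _as_stratum_data(strata, variables)
    _validate(sd)
    starts = sd.offsets[:-1]
    idx = sd.stratum_index
    k = sd.X.shape[1]

    # a covariate with zero within-stratum variance everywhere carries no
    # conditional information
    stratum_means = (np.add.reduceat(sd.X, starts, axis=0)
                     / np.diff(sd.offsets)[:, None])
    centered = sd.X - stratum_means[idx]
    no_info = np.flatnonzero(np.abs(centered).max(axis=0) < 1e-12)
    if no_info.size:
        names = [sd.variables[j] for j in no_info]
        raise FitError(f"covariate(s) constant within every stratum, no "
                       f"conditional information: {names}")

    beta = np.zeros(k)
    ll = conditional_loglik(beta, sd)
    null_ll = ll
    converged = False
    singular = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = sd.X @ beta
        mx = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - mx[idx])
        denom = np.add.reduceat(w, starts)
        p = w / denom[idx]
        mu = np.add.reduceat(sd.X * p[:, None], starts, axis=0)  # E_s[x]
        grad = sd.X[sd.y == 1.0].sum(axis=0) - mu.sum(axis=0)
        H = (sd.X * p[:, None]).T @ sd.X - mu.T @ mu   # sum_s Cov_s[x]
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            singular = True
            break
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = conditional_loglik(cand, sd)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        beta, ll = cand, ll_new
        if np.linalg.norm(grad) < tol:
            converged = True
            break
    # recheck gradient at the final point
    if not converged and not singular:
        eta = sd.X @ beta
        mx = np.maximum.reduceat(eta, starts)
        w = np.exp(eta - mx[idx])
        denom = np.add.reduceat(w, starts)
        p = w / denom[idx]
        mu = np.add.reduceat(sd.X * p[:, None], starts, axis=0)
        grad = sd.X[sd.y == 1.0].sum(axis=0) - mu.sum(axis=0)
        converged = bool(np.linalg.norm(grad) < tol)

    eta = sd.X @ beta
    mx = np.maximum.reduceat(eta, starts)
    w = np.exp(eta - mx[idx])
    denom = np.add.reduceat(w, starts)
    p = w / denom[idx]
    mu = np.add.reduceat(sd.X * p[:, None], starts, axis=0)
    H = (sd.X * p[:, None]).T @ sd.X - mu.T @ mu
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
        converged = False
    with np.errstate(invalid="ignore"):
        wald_p = stats.chi2.sf((beta / se) ** 2, df=1)
    return ConditionalFit(variables=sd.variables, beta=beta, se=se,
                          wald_p=wald_p, loglik=ll, null_loglik=null_ll,
                          converged=converged, iterations=it,
                          n_strata=sd.n_strata)


def discriminant_score(fit: ConditionalFit, data) -> np.ndarray:
    """Discriminant score x' beta per subject.

    This is the logit of the conditional-logistic function value
    1 / (1 + exp(-x' beta)); no stratum information is needed, so the
    score applies identically to study subjects, unmatched test-set
    subjects and external records.
    """
    if isinstance(data, pd.DataFrame):
        missing = [v for v in fit.variables if v not in data.columns]
        if missing:
            raise SchemaError(
                f"cohort is missing selected amino acid(s): {missing}")
        X = data.loc[:, list(fit.variables)].to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(data, dtype=float))
    return X @ fit.beta
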