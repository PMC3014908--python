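"""Univariate and principal-component profiling of aminograms.

Per-amino-acid group comparisons (Mann-Whitney U, rank-statistic ROC AUC),
z-standardisation with the population (divide-by-n) SD, PCA of the
standardised pooled matrix with the Kaiser retention rule, per-component
group tests on the scores, and contributor extraction by squared loading.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError
from .synthetic_data import AMINO_ACIDS

__all__ = [
    "MannWhitneyResult", "StandardizedMatrix", "PCAResult",
    "ContributorResult", "mann_whitney", "summarize_amino_acids",
    "standardize", "pca", "extract_contributors",
]

#: Largest min(n_x, n_y) for which the exact permutation p-value is used.
EXACT_MAX_N = 8


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # pairs with x > y plus half the ties
    p: float          # two-sided
    method: str       # "exact" | "asymptotic"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #(x > y) + 0.5 * #(x == y), via midranks."""
    nx, ny = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def mann_whitney(x, y) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test.

    U counts (x, y) pairs with x > y plus half the ties.  The p-value comes
    from exact enumeration of the permutation distribution when
    min(n) <= 8 (ties handled exactly), otherwise from the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    u = _u_statistic(x, y)
    center = nx * ny / 2.0

    from math import comb
    if min(nx, ny) <= EXACT_MAX_N and comb(nx + ny, nx) <= 200_000:
        pooled = np.concatenate([x, y])
        obs = abs(u - center)
        hits = total = 0
        for comb in itertools.combinations(range(nx + ny), nx):
            mask = np.zeros(nx + ny, dtype=bool)
            mask[list(comb)] = True
            xs, ys = pooled[mask], pooled[~mask]
            u_perm = (np.sum(xs[:, None] > ys[None, :])
                      + 0.5 * np.sum(xs[:, None] == ys[None, :]))
            if abs(u_perm - center) >= obs - 1e-12:
                hits += 1
            total += 1
        return MannWhitneyResult(u=u, p=hits / total, method="exact")

    n = nx + ny
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:          # all pooled values identical
        return MannWhitneyResult(u=u, p=1.0, method="asymptotic")
    z = (abs(u - center) - 0.5) / np.sqrt(var_u)
    p = min(1.0, 2.0 * stats.norm.sf(z))
    return MannWhitneyResult(u=u, p=p, method="asymptotic")


@dataclass
class StandardizedMatrix:
    """Column-standardised concentration matrix.

    z[i, j] = (x[i, j] - mean_j) / population SD_j (divide by n, not n-1),
    with the column means and scales retained for re-projection of new
    subjects.
    """

    z: np.ndarray                  # n x p, unitless
    column_means: np.ndarray       # μM
    column_scales: np.ndarray      # μM, population SD
    columns: tuple[str, ...]

    def project(self, X) -> np.ndarray:
        """Standardise new data with the stored means/scales."""
        X = np.asarray(X, dtype=float)
        return (X - self.column_means) / self.column_scales


def standardize(matrix, columns: tuple[str, ...] | None = None
                ) -> StandardizedMatrix:
    """Z-transform each column with its mean and population SD.

    Raises :class:`~aminoscreen.errors.SchemaError` naming any constant
    column (zero denominator).
    """
    if isinstance(matrix, pd.DataFrame):
        if columns is None:
            columns = tuple(matrix.columns)
        X = matrix.loc[:, list(columns)].to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if columns is None:
            columns = tuple(f"col{j}" for j in range(X.shape[1]))
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    degenerate = [columns[j] for j in np.flatnonzero(scales == 0)]
    if degenerate:
        raise SchemaError(f"constant column(s), cannot standardise: "
                          f"{degenerate}")
    return StandardizedMatrix(z=(X - means) / scales, column_means=means,
                              column_scales=scales, columns=tuple(columns))


@dataclass
class PCAResult:
    """Eigen-decomposition of the correlation matrix of standardised data.

    Loadings are orthonormal eigenvector columns, oriented so each
    column's largest-magnitude entry is positive; eigenvalues are
    non-increasing and sum to the number of variables; scores are the
    projections of the rows; pc_pvalues are two-sided Mann-Whitney
    p-values of case vs control scores per component (when labels are
    supplied).
    """

    loadings: np.ndarray           # p x p
    eigenvalues: np.ndarray        # p
    scores: np.ndarray             # n x p
    pc_pvalues: np.ndarray | None  # p, or None without labels
    columns: tuple[str, ...]
    correlation: np.ndarray        # p x p sample correlation of z


def pca(z: StandardizedMatrix | np.ndarray,
        labels: np.ndarray | None = None) -> PCAResult:
    """PCA of a standardised matrix via the correlation-matrix eigenproblem.

    ``labels`` (optional) is a per-row array of "case"/"control" used for
    the per-component score tests.
    """
    if isinstance(z, StandardizedMatrix):
        Z, columns = z.z, z.columns
    else:
        Z = np.asarray(z, dtype=float)
        columns = tuple(f"col{j}" for j in range(Z.shape[1]))
    n, p = Z.shape
    if n < p:
        raise ValueError(f"need at least as many rows ({n}) as columns ({p})")
    C = Z.T @ Z / n
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for k in range(p):
        top = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[top, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    scores = Z @ eigvecs
    pvals = None
    if labels is not None:
        labels = np.asarray(labels)
        case_mask = labels == "case"
        if case_mask.sum() == 0 or case_mask.sum() == n:
            raise ValueError("labels must contain both groups")
        pvals = np.array([
            mann_whitney(scores[case_mask, k], scores[~case_mask, k]).p
            for k in range(p)])
    return PCAResult(loadings=eigvecs, eigenvalues=eigvals, scores=scores,
                     pc_pvalues=pvals, columns=columns, correlation=C)


@dataclass
class ContributorResult:
    retained: list[int]                 # PCs with eigenvalue > kaiser cut
    significant: list[int]              # retained PCs with score p < alpha
    contributors: dict[int, list[str]]  # per significant PC
    panel: list[str]                    # union, in canonical column order


def extract_contributors(result: PCAResult, alpha: float = 0.05,
                         variance_threshold: float = 0.05,
                         eigenvalue_cut: float = 1.0) -> ContributorResult:
    """Contributing variables of the retained, group-significant PCs.

    Retains components with eigenvalue > ``eigenvalue_cut`` (Kaiser rule);
    keeps those whose score-wise Mann-Whitney p < ``alpha``; a variable
    contributes to a component when its squared loading exceeds
    ``variance_threshold``.  Returns per-component contributor lists and
    their union as a panel ordered like the input columns.
    """
    if result.pc_pvalues is None:
        raise ValueError("PCA must be computed with labels to extract "
                         "contributors")
    retained = [k for k in range(len(result.eigenvalues))
                if result.eigenvalues[k] > eigenvalue_cut]
    significant = [k for k in retained if result.pc_pvalues[k] < alpha]
    contributors = {}
    for k in significant:
        sq = result.loadings[:, k] ** 2
        contributors[k] = [result.columns[j]
                           for j in np.flatnonzero(sq > variance_threshold)]
    union = set().union(*contributors.values()) if contributors else set()
    panel = [c for c in result.columns if c in union]
    return ContributorResult(retained=retained, significant=significant,
                             contributors=contributors, panel=panel)


def summarize_amino_acids(cases: pd.DataFrame,
                          controls: pd.DataFrame) -> pd.DataFrame:
    """Per-amino-acid group comparison table.

    Columns: amino_acid, mean_case, sd_case, mean_control, sd_control,
    p_value (Mann-Whitney), auc (rank-statistic univariate ROC AUC,
    oriented so auc >= 0.5).  SDs are sample (n-1) SDs, matching the usual
    reporting convention.
    """
    from .evaluation import auc as _auc

    for name, df in (("cases", cases), ("controls", controls)):
        missing = [a for a in AMINO_ACIDS if a not in df.columns]
        if missing:
            raise SchemaError(f"{name} table is missing amino-acid "
                              f"column(s): {missing}")
    rows = []
    for a in AMINO_ACIDS:
        x = cases[a].to_numpy(dtype=float)
        y = controls[a].to_numpy(dtype=float)
        mw = mann_whitney(x, y)
        a_raw = _auc(x, y)
        rows.append({
            "amino_acid": a,
            "mean_case": x.mean(), "sd_case": x.std(ddof=1),
            "mean_control": y.mean(), "sd_control": y.std(ddof=1),
            "p_value": mw.p,
            "auc": max(a_raw, 1.0 - a_raw),
        })
    return pd.DataFrame(rows)
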