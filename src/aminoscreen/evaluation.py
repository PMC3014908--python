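"""ROC evaluation of discriminant scores, overall and by subgroup.

AUC is the Mann-Whitney rank statistic — the probability that a random
case outscores a random control, with ties earning half credit — so it
agrees exactly with trapezoidal integration of the empirical ROC curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .clogit import ConditionalFit, discriminant_score
from .synthetic_data import GeneratorConfig, STAGES, HISTOLOGIES, build_covariance

__all__ = ["auc", "roc_points", "subgroup_auc", "population_auc"]

#: patient subgroups smaller than this are flagged low-n
LOW_N = 3


def auc(case_scores, control_scores) -> float:
    """Rank-statistic ROC AUC: (#pairs case>control + 0.5·ties) / (n1·n0)."""
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    if case_scores.size == 0 or control_scores.size == 0:
        raise ValueError("both score sets must be non-empty")
    n1, n0 = case_scores.size, control_scores.size
    ranks = stats.rankdata(np.concatenate([case_scores, control_scores]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_points(case_scores, control_scores) -> pd.DataFrame:
    """Full empirical ROC curve: FPR and TPR at every threshold."""
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    y = np.concatenate([np.ones(case_scores.size),
                        np.zeros(control_scores.size)])
    scores = np.concatenate([case_scores, control_scores])
    fpr, tpr, thresholds = _sk_roc_curve(y, scores)
    return pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})


def subgroup_auc(patients: pd.DataFrame, controls: pd.DataFrame,
                 fit: ConditionalFit) -> pd.DataFrame:
    """Discriminant-score AUC per stage and histology subgroup.

    Each patient subgroup is scored against ALL controls of the same data
    set.  Rows: dimension ('overall'|'stage'|'histology'), level,
    n_patients, auc (NA for empty subgroups), low_n flag (< 3 patients).
    """
    control_scores = discriminant_score(fit, controls)
    patient_scores = discriminant_score(fit, patients)
    rows = [{
        "dimension": "overall", "level": "all",
        "n_patients": len(patients),
        "auc": auc(patient_scores, control_scores),
        "low_n": len(patients) < LOW_N,
    }]
    for dimension, levels, column in (
            ("stage", STAGES, "stage"),
            ("histology", HISTOLOGIES, "histology")):
        if column not in patients.columns:
            continue
        for level in levels:
            mask = (patients[column] == level).to_numpy()
            n = int(mask.sum())
            rows.append({
                "dimension": dimension, "level": level, "n_patients": n,
                "auc": auc(patient_scores[mask], control_scores)
                if n else np.nan,
                "low_n": n < LOW_N,
            })
    return pd.DataFrame(rows)


def population_auc(config: GeneratorConfig, variables: list[str],
                   beta: np.ndarray | None = None) -> float:
    """Closed-form AUC of a linear score under the generator's model.

    For a linear score s = b'x with Gaussian groups, AUC =
    Phi(b'Δ / sqrt(b'Σ_case b + b'Σ_control b)) where Δ is the case-minus-
    control mean difference over ``variables``.  With ``beta`` omitted the
    pooled-covariance discriminant b = ((Σ_case+Σ_control)/2)^{-1} Δ is
    used — the large-sample direction of the fitted logistic model and the
    analytic oracle for the empirical panel AUC.
    """
    names = list(config.amino_acid_names)
    idx = [names.index(v) for v in variables]
    delta = (config.means("case") - config.means("control"))[idx]
    sigma_case = build_covariance(config, "case")[np.ix_(idx, idx)]
    sigma_control = build_covariance(config, "control")[np.ix_(idx, idx)]
    if beta is None:
        beta = np.linalg.solve((sigma_case + sigma_control) / 2.0, delta)
    beta = np.asarray(beta, dtype=float)
    num = float(beta @ delta)
    den = float(np.sqrt(beta @ sigma_case @ beta
                        + beta @ sigma_control @ beta))
    return float(stats.norm.cdf(num / den))
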