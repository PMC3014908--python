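"""End-to-end orchestration: simulate → match → profile → select → fit →
score → report, driven by a single config and seed.

Every source of randomness flows from the run seed through named
substreams (generator, matching, test set), so a run is fully reproducible
from (config, seed) and the summary JSON is byte-identical across
repeats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .synthetic_data import (AMINO_ACIDS, GeneratorConfig,
                             load_default_params, generate_cohort,
                             matching_pool_margins)
from .matching import match_controls, matched_dataframe
from .univariate_pca import (standardize, pca, extract_contributors,
                             summarize_amino_acids)
from .selection import exhaustive_search, count_subsets
from .clogit import fit_conditional, strata_from_matched, discriminant_score
from .evaluation import auc, roc_points, subgroup_auc
from .io import read_cohort, write_cohort, write_scores, write_json

__all__ = ["RunConfig", "run_pipeline", "substream_seed"]

logger = logging.getLogger(__name__)

#: advisory cap on the subset size of the exhaustive search
K_MAX_POLICY = 6


def substream_seed(seed: int, name: str) -> int:
    """Derive a named child seed (< 2^31) from the run seed."""
    return (int(seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    Either cohort CSV paths (``cases_csv`` + ``pool_csv``) or generator
    settings; generator settings are always available as defaults, so the
    no-paths case falls back to simulation.
    """

    cases_csv: str | None = None
    pool_csv: str | None = None
    n_cases: int = 141
    n_control_pool: int = 4000
    ratio: int = 3                      # controls per case
    caliper: float = 5.0                # years
    selection_pool: str | list[str] = "contributors"  # or "all" / list
    k_max: int = 3
    workers: int = 1
    penalty: bool = True                # keep the 2(k+1) AIC penalty
    test_n_patients: int = 162
    test_n_controls: int = 3917
    run_test_set: bool = True
    seed: int = 0
    outdir: str = "aminoscreen-run"

    def __post_init__(self):
        if (self.cases_csv is None) != (self.pool_csv is None):
            raise ConfigurationError(
                "cases_csv and pool_csv must be given together")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): "
                                     f"{sorted(unknown)}")
        return cls(**raw)

    def canonical_json(self) -> str:
        """Scientific settings only: the output location does not alter
        results and is excluded from the provenance hash."""
        settings = dataclasses.asdict(self)
        settings.pop("outdir")
        return json.dumps(settings, sort_keys=True)


def run_pipeline(config: RunConfig,
                 generator: GeneratorConfig | None = None) -> dict:
    """Execute the full screening analysis and write all artifacts.

    Returns the machine-readable summary (also written to
    ``<outdir>/summary.json``): selected subset with its cross-validated
    AIC, conditional coefficients/SEs/p-values, overall and subgroup AUCs
    for the study set and (optionally) an independent test set, plus a
    provenance block (config hash, seed, versions).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = generator if generator is not None else load_default_params()
    seed = int(config.seed)

    # --- cohorts -----------------------------------------------------
    if config.cases_csv:
        logger.info("reading cohorts from %s / %s",
                    config.cases_csv, config.pool_csv)
        cases = read_cohort(config.cases_csv)
        pool = read_cohort(config.pool_csv)
    else:
        logger.info("simulating %d cases and %d pool controls",
                    config.n_cases, config.n_control_pool)
        cases = generate_cohort(gen, "case", config.n_cases,
                                seed=substream_seed(seed, "cases"))
        pool = generate_cohort(gen, "control", config.n_control_pool,
                               seed=substream_seed(seed, "pool"),
                               demographics=matching_pool_margins(gen))
        write_cohort(cases, outdir / "cases.csv")
        write_cohort(pool, outdir / "pool.csv")

    # --- matching ----------------------------------------------------
    strata = match_controls(cases, pool, ratio=config.ratio,
                            caliper=config.caliper,
                            seed=substream_seed(seed, "matching"))
    matched = matched_dataframe(strata, cases, pool)
    write_cohort(matched, outdir / "matched.csv")
    controls = matched[matched["group"] == "control"].reset_index(drop=True)
    study = matched

    # --- profiling ---------------------------------------------------
    profile = summarize_amino_acids(cases, controls)
    profile.to_csv(outdir / "profile.csv", index=False)
    std = standardize(study, columns=AMINO_ACIDS)
    pca_result = pca(std, labels=study["group"].to_numpy())
    loadings = pd.DataFrame(pca_result.loadings[:, :5],
                            index=AMINO_ACIDS,
                            columns=[f"PC{k+1}" for k in range(5)])
    loadings.to_csv(outdir / "loadings.csv")
    contributors = extract_contributors(pca_result)
    write_json({
        "retained_pcs": [k + 1 for k in contributors.retained],
        "significant_pcs": [k + 1 for k in contributors.significant],
        "contributors": {f"PC{k+1}": v
                         for k, v in contributors.contributors.items()},
        "panel": contributors.panel,
    }, outdir / "contributors.json")

    # --- model selection ---------------------------------------------
    if config.selection_pool == "all":
        pool_vars = list(AMINO_ACIDS)
    elif config.selection_pool == "contributors":
        pool_vars = contributors.panel
    else:
        pool_vars = list(config.selection_pool)
    k_max = min(config.k_max, len(pool_vars))
    if config.k_max > K_MAX_POLICY:
        logger.warning("k_max=%d exceeds the subset-size policy cap of %d; "
                       "honouring it as given", config.k_max, K_MAX_POLICY)
    logger.info("exhaustive search over %d candidates (%d variables, "
                "k_max=%d)", count_subsets(len(pool_vars), k_max),
                len(pool_vars), k_max)
    candidates = exhaustive_search(study, variables=pool_vars, k_max=k_max,
                                   workers=config.workers,
                                   penalty=config.penalty)
    top = pd.DataFrame([{
        "subset": "+".join(c.subset), "size": len(c.subset),
        "cv_aic": c.cv_aic, "converged": c.converged,
    } for c in candidates[:50]])
    top.to_csv(outdir / "candidates.csv", index=False)
    best = candidates[0]

    # --- conditional fit and scoring ---------------------------------
    sd = strata_from_matched(study, list(best.subset))
    fit = fit_conditional(sd)
    write_json({
        "variables": list(fit.variables),
        "beta": fit.beta.tolist(),
        "se": fit.se.tolist(),
        "wald_p": fit.wald_p.tolist(),
        "loglik": fit.loglik,
        "converged": bool(fit.converged),
    }, outdir / "fit.json")

    study_scores = study.assign(score=discriminant_score(fit, study))
    write_scores(study_scores[["subject_id", "group", "stratum_id",
                               "score"]], outdir / "scores_study.csv")
    case_scores = study_scores.loc[study_scores["group"] == "case", "score"]
    ctrl_scores = study_scores.loc[study_scores["group"] == "control",
                                   "score"]
    study_auc = auc(case_scores, ctrl_scores)
    roc_points(case_scores, ctrl_scores).to_csv(
        outdir / "roc_study.csv", index=False)
    study_subgroups = subgroup_auc(
        study[study["group"] == "case"].reset_index(drop=True),
        controls, fit)
    study_subgroups.to_csv(outdir / "subgroup_auc_study.csv", index=False)

    summary: dict = {
        "n_cases": int((study["group"] == "case").sum()),
        "n_matched_controls": int((study["group"] == "control").sum()),
        "selection": {
            "pool": pool_vars, "k_max": k_max,
            "n_candidates": count_subsets(len(pool_vars), k_max),
            "best_subset": list(best.subset),
            "cv_aic": best.cv_aic,
        },
        "conditional_fit": {
            "variables": list(fit.variables),
            "beta": fit.beta.tolist(),
            "se": fit.se.tolist(),
            "wald_p": fit.wald_p.tolist(),
            "converged": bool(fit.converged),
        },
        "study_auc": study_auc,
        "study_subgroup_auc": study_subgroups.to_dict(orient="records"),
        "pca": {
            "eigenvalues": pca_result.eigenvalues[:5].tolist(),
            "panel": contributors.panel,
        },
    }

    # --- independent test set ----------------------------------------
    if config.run_test_set and not config.cases_csv:
        test_patients = generate_cohort(
            gen, "case", config.test_n_patients,
            seed=substream_seed(seed, "test-patients"))
        test_controls = generate_cohort(
            gen, "control", config.test_n_controls,
            seed=substream_seed(seed, "test-controls"))
        t_case = discriminant_score(fit, test_patients)
        t_ctrl = discriminant_score(fit, test_controls)
        summary["test_auc"] = auc(t_case, t_ctrl)
        test_subgroups = subgroup_auc(test_patients, test_controls, fit)
        test_subgroups.to_csv(outdir / "subgroup_auc_test.csv", index=False)
        summary["test_subgroup_auc"] = test_subgroups.to_dict(
            orient="records")

    summary["provenance"] = {
        "config_sha256": hashlib.sha256(
            config.canonical_json().encode()).hexdigest(),
        "seed": seed,
        "aminoscreen_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    write_json(summary, outdir / "summary.json")
    return summary
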