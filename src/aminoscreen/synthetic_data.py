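"""Seeded synthetic plasma-aminogram cohorts.

The original NSCLC screening cohorts were never deposited, so every
downstream stage of the pipeline is exercised on synthetic cohorts whose
statistical structure is calibrated to the published summary tables:

* 21 plasma free amino-acid concentrations (μM) drawn from a multivariate
  normal whose group-wise marginal means and SDs equal the published
  patient/control values exactly, with a configurable block correlation
  structure (branched-chain, aromatic and urea-cycle blocks over a weak
  baseline correlation);
* demographics (age, gender, smoking status, BMI) drawn from the published
  study-set margins, with age truncated to the published ranges by
  resampling;
* disease stage and histological type for cases only.

Draws with any non-positive concentration are rejected and redrawn, which
keeps concentrations physical while leaving the published moments as exact
population targets (all configured means sit ≥ 2.8 SDs above zero, so
rejection is rare and the induced bias is negligible).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "AMINO_ACIDS",
    "matching_pool_margins",
    "GeneratorConfig",
    "SubjectRecord",
    "DemographicMargins",
    "load_default_params",
    "build_covariance",
    "correlation_matrix",
    "generate_cohort",
]

#: Canonical three-letter amino-acid codes, in the fixed reporting order.
#: ABA is α-aminobutyric acid.
AMINO_ACIDS: tuple[str, ...] = (
    "Thr", "Ser", "Asn", "Glu", "Gln", "Pro", "Gly", "Ala", "Cit", "ABA",
    "Val", "Met", "Ile", "Leu", "Tyr", "Phe", "His", "Trp", "Orn", "Lys",
    "Arg",
)

# Group-wise plasma concentration marginals, μM: (case mean, case SD,
# control mean, control SD), calibrated to the published study-set table.
_MARGINALS: dict[str, tuple[float, float, float, float]] = {
    "Thr": (115.6, 28.6, 115.9, 25.4),
    "Ser": (117.1, 19.9, 111.4, 17.9),
    "Asn": (45.1, 8.2, 44.8, 7.2),
    "Glu": (46.7, 19.4, 45.7, 19.5),
    "Gln": (580.5, 93.3, 587.9, 83.5),
    "Pro": (168.0, 43.6, 150.9, 41.4),
    "Gly": (263.6, 63.2, 237.0, 57.3),
    "Ala": (422.3, 97.4, 383.7, 88.9),
    "Cit": (34.4, 10.6, 33.2, 8.3),
    "ABA": (24.2, 8.4, 23.2, 6.9),
    "Val": (244.8, 47.5, 239.8, 46.1),
    "Met": (29.4, 6.1, 28.0, 5.2),
    "Ile": (84.3, 22.1, 69.7, 17.5),
    "Leu": (131.8, 34.3, 122.4, 27.6),
    "Tyr": (80.7, 15.6, 75.8, 15.5),
    "Phe": (67.9, 12.2, 63.9, 11.2),
    "His": (77.3, 15.0, 80.8, 10.7),
    "Trp": (59.3, 12.0, 59.8, 10.9),
    "Orn": (67.6, 19.7, 54.4, 12.3),
    "Lys": (211.5, 36.2, 200.3, 34.1),
    "Arg": (101.3, 21.6, 98.1, 17.8),
}

#: Biologically motivated default correlation blocks: branched-chain amino
#: acids, aromatic amino acids, and the urea-cycle trio, over a weak
#: baseline.  block name -> (member amino acids, within-block correlation).
DEFAULT_CORRELATION_BLOCKS: dict[str, tuple[tuple[str, ...], float]] = {
    "bcaa": (("Val", "Ile", "Leu"), 0.7),
    "aromatic": (("Tyr", "Phe", "Trp"), 0.5),
    "urea_cycle": (("Cit", "Orn", "Arg"), 0.4),
}
DEFAULT_BASELINE_RHO: float = 0.2

STAGES: tuple[str, ...] = ("I", "II", "III", "IV")
HISTOLOGIES: tuple[str, ...] = ("adenocarcinoma", "squamous", "other")


@dataclass(frozen=True)
class DemographicMargins:
    """Categorical and normal margins for one group's demographics."""

    gender: dict[str, float]           # male/female probabilities
    smoking: dict[str, float]          # never/ex/current probabilities
    age_mean: float                    # years
    age_sd: float                      # years
    age_range: tuple[float, float]     # truncation bounds, years
    bmi_mean: float                    # kg/m^2
    bmi_sd: float                      # kg/m^2
    age_uniform: bool = False          # uniform over age_range instead of
                                       # truncated normal


# Study-set margins.  Subjects with unknown smoking status are dropped from
# the published counts before normalisation.
_CASE_DEMOGRAPHICS = DemographicMargins(
    gender={"male": 93 / 141, "female": 48 / 141},
    smoking={"never": 42 / 136, "ex": 15 / 136, "current": 79 / 136},
    age_mean=62.7, age_sd=9.2, age_range=(34.0, 83.0),
    bmi_mean=22.6, bmi_sd=2.8,
)
_CONTROL_DEMOGRAPHICS = DemographicMargins(
    gender={"male": 279 / 423, "female": 144 / 423},
    smoking={"never": 126 / 408, "ex": 45 / 408, "current": 237 / 408},
    age_mean=61.1, age_sd=8.7, age_range=(32.0, 82.0),
    bmi_mean=23.0, bmi_sd=3.1,
)
_STAGE_MARGINS = {"I": 69 / 141, "II": 8 / 141, "III": 39 / 141, "IV": 25 / 141}
_HISTOLOGY_MARGINS = {
    "adenocarcinoma": 100 / 140, "squamous": 36 / 140, "other": 4 / 140,
}


@dataclass
class GeneratorConfig:
    """Full parameterisation of the synthetic-cohort generator.

    Amino-acid marginals are per-group means/SDs in μM; the joint
    distribution is multivariate normal with a shared block correlation
    matrix.  Demographic margins are per-group; stage and histology margins
    apply to cases only.
    """

    amino_acid_names: tuple[str, ...] = AMINO_ACIDS
    mean_case: dict[str, float] = field(
        default_factory=lambda: {a: v[0] for a, v in _MARGINALS.items()})
    sd_case: dict[str, float] = field(
        default_factory=lambda: {a: v[1] for a, v in _MARGINALS.items()})
    mean_control: dict[str, float] = field(
        default_factory=lambda: {a: v[2] for a, v in _MARGINALS.items()})
    sd_control: dict[str, float] = field(
        default_factory=lambda: {a: v[3] for a, v in _MARGINALS.items()})
    correlation_blocks: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=lambda: dict(DEFAULT_CORRELATION_BLOCKS))
    baseline_rho: float = DEFAULT_BASELINE_RHO
    demographics_case: DemographicMargins = _CASE_DEMOGRAPHICS
    demographics_control: DemographicMargins = _CONTROL_DEMOGRAPHICS
    stage_margins: dict[str, float] = field(
        default_factory=lambda: dict(_STAGE_MARGINS))
    histology_margins: dict[str, float] = field(
        default_factory=lambda: dict(_HISTOLOGY_MARGINS))
    n_cases: int = 141
    n_control_pool: int = 4000
    seed: int = 0

    def means(self, group: str) -> np.ndarray:
        src = self.mean_case if group == "case" else self.mean_control
        return np.array([src[a] for a in self.amino_acid_names], dtype=float)

    def sds(self, group: str) -> np.ndarray:
        src = self.sd_case if group == "case" else self.sd_control
        return np.array([src[a] for a in self.amino_acid_names], dtype=float)

    def validate(self) -> None:
        for group in ("case", "control"):
            if np.any(self.means(group) <= 0):
                raise ConfigurationError(f"non-positive mean in group {group!r}")
            if np.any(self.sds(group) <= 0):
                raise ConfigurationError(f"non-positive SD in group {group!r}")
        for name, margin in [
            ("gender(case)", self.demographics_case.gender),
            ("smoking(case)", self.demographics_case.smoking),
            ("gender(control)", self.demographics_control.gender),
            ("smoking(control)", self.demographics_control.smoking),
            ("stage", self.stage_margins),
            ("histology", self.histology_margins),
        ]:
            total = sum(margin.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"margin {name} sums to {total!r}, expected 1")
        # raises ConfigurationError if the implied correlation is not PD
        correlation_matrix(self)

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: demographics, clinical annotations, 21-AA aminogram."""

    subject_id: str
    group: str                     # "case" | "control"
    age: float                     # years
    gender: str                    # "male" | "female"
    smoking: str                   # "never" | "ex" | "current"
    bmi: float                     # kg/m^2
    stage: str                     # I..IV for cases, "NA" for controls
    histology: str                 # class for cases, "NA" for controls
    aa: dict[str, float]           # μM per amino acid

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        return cls(
            subject_id=str(row["subject_id"]), group=row["group"],
            age=float(row["age"]), gender=row["gender"],
            smoking=row["smoking"], bmi=float(row["bmi"]),
            stage=str(row["stage"]), histology=str(row["histology"]),
            aa={a: float(row[a]) for a in AMINO_ACIDS},
        )


def matching_pool_margins(config: GeneratorConfig) -> DemographicMargins:
    """Demographics for a control recruitment pool designed for matching.

    Gender and smoking margins follow the case margins, and age is uniform
    over the case age range, so every case — including those at the age
    extremes in small gender x smoking cells — has matchable control
    density at a tight caliper.  Aminograms are unaffected (they are
    independent of demographics), so the pool's concentration marginals
    remain the configured control values.
    """
    case = config.demographics_case
    control = config.demographics_control
    return DemographicMargins(
        gender=dict(case.gender), smoking=dict(case.smoking),
        age_mean=(case.age_range[0] + case.age_range[1]) / 2.0,
        age_sd=(case.age_range[1] - case.age_range[0]) / np.sqrt(12.0),
        age_range=case.age_range,
        bmi_mean=control.bmi_mean, bmi_sd=control.bmi_sd,
        age_uniform=True,
    )


def load_default_params() -> GeneratorConfig:
    """Default generator configuration calibrated to the published study set.

    The 21 case/control means and SDs equal the published concentration
    table; demographic, stage and histology margins equal the published
    study-set characteristics (unknown categories dropped); the correlation
    structure is the default BCAA/aromatic/urea-cycle block design.
    """
    config = GeneratorConfig()
    config.validate()
    return config


def correlation_matrix(config: GeneratorConfig) -> np.ndarray:
    """Block correlation matrix R shared by both groups.

    Off-diagonal entries default to ``baseline_rho``; pairs inside a named
    block get that block's correlation.  Raises
    :class:`~aminoscreen.errors.ConfigurationError` naming the offending
    block if R is not positive definite.
    """
    names = list(config.amino_acid_names)
    p = len(names)
    index = {a: j for j, a in enumerate(names)}
    R = np.full((p, p), float(config.baseline_rho))
    np.fill_diagonal(R, 1.0)
    for block_name, (members, rho) in config.correlation_blocks.items():
        unknown = [m for m in members if m not in index]
        if unknown:
            raise ConfigurationError(
                f"correlation block {block_name!r} names unknown amino "
                f"acids: {unknown}")
        idx = [index[m] for m in members]
        for a in idx:
            for b in idx:
                if a != b:
                    R[a, b] = float(rho)
    if np.linalg.eigvalsh(R).min() <= 0:
        # find a single block whose removal restores positive definiteness
        for block_name in config.correlation_blocks:
            reduced = config.replace(correlation_blocks={
                k: v for k, v in config.correlation_blocks.items()
                if k != block_name})
            try:
                correlation_matrix(reduced)
            except ConfigurationError:
                continue
            raise ConfigurationError(
                f"correlation matrix is not positive definite; block "
                f"{block_name!r} is responsible")
        raise ConfigurationError(
            "correlation matrix is not positive definite "
            "(no single block is responsible)")
    return R


def build_covariance(config: GeneratorConfig, group: str) -> np.ndarray:
    """Covariance matrix D·R·D (μM²) for one group.

    D is the diagonal matrix of the group's SDs and R the shared block
    correlation matrix.
    """
    if group not in ("case", "control"):
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    sds = config.sds(group)
    R = correlation_matrix(config)
    return R * np.outer(sds, sds)


def _positivity_adjusted_params(mean: np.ndarray, sd: np.ndarray,
                                R: np.ndarray,
                                n_iter: int = 8
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Underlying MVN parameters whose positivity-rejected draws hit the
    configured moments.

    Rejecting any draw with a non-positive coordinate truncates the
    distribution, which inflates the mean and shrinks the SD of every
    column whose mean sits only a few SDs above zero (Glu, at ~2.4 SD, is
    the binding case) and — through the correlation structure — nudges
    every other column upward.  Solving the truncated-normal moment
    relations by fixed point,

        E[X | X > 0]   = m + s * h(m/s),          h = phi/Phi (hazard)
        Var[X | X > 0] = s^2 * (1 - z*h - h^2),   z = m/s,

    with first-order cross terms m_j -= s_j * (R @ h)_j, yields draw
    parameters (m, s) such that the accepted draws' means and SDs equal
    the configured targets to well within Monte-Carlo resolution at
    n = 10^5.  For columns many SDs above zero the adjustment vanishes.
    """
    from scipy import stats as _stats

    m, s = mean.astype(float).copy(), sd.astype(float).copy()
    # only adjust columns comfortably above zero; heavier truncation has
    # no reliable moment inversion and such configs fail the rejection-
    # rate check downstream instead
    active = mean / sd >= 2.0
    for _ in range(n_iter):
        z = np.clip(m / s, -6.0, None)
        # hazard of falling below zero; numerically zero far from the axis
        lam = np.where(z < 8.0,
                       _stats.norm.pdf(z) / _stats.norm.cdf(z), 0.0)
        delta = z * lam + lam**2          # own-truncation variance loss
        cross = (R**2) @ delta - delta    # rho^2-weighted loss from others
        var_factor = np.clip((1.0 - delta) * (1.0 - cross), 0.25, None)
        s = np.where(active, sd / np.sqrt(var_factor), sd)
        m = np.where(active, mean - s * (R @ lam), mean)
    return m, s


def _sample_categorical(rng: np.random.Generator, margin: dict[str, float],
                        n: int) -> np.ndarray:
    keys = list(margin.keys())
    probs = np.array([margin[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(keys, dtype=object), size=n, p=probs)


def _sample_truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                             lo: float, hi: float, n: int) -> np.ndarray:
    """Normal draws truncated to [lo, hi] by resampling."""
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(config: GeneratorConfig, group: str, n: int,
                    seed: int | None = None,
                    id_prefix: str | None = None,
                    demographics: DemographicMargins | str | None = None,
                    ) -> pd.DataFrame:
    """Draw a synthetic cohort of ``n`` subjects from one group.

    Aminograms come from the group's multivariate normal (non-positive
    draws rejected and redrawn); demographics, stage and histology are
    sampled independently from the group's margins.  Deterministic given
    ``seed`` (defaults to ``config.seed``).

    ``demographics`` overrides the demographic margins without touching
    the aminogram marginals: a :class:`DemographicMargins`, or "case" /
    "control" to borrow the other group's margins.  Aminograms are
    independent of demographics, so this only shifts age/gender/smoking/
    BMI.  The main use is a control recruitment pool whose demographics
    overlap the cases, so that 1:m matching at a tight caliper is
    feasible at every case age.

    Returns a DataFrame with the fixed cohort schema: subject_id, group,
    age, gender, smoking, bmi, stage, histology, then the 21 amino-acid
    columns in canonical order.
    """
    if n <= 0:
        raise ValueError(f"n must be >= 1, got {n}")
    if group not in ("case", "control"):
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(int(seed))

    R = correlation_matrix(config)
    draw_mean, draw_sd = _positivity_adjusted_params(
        config.means(group), config.sds(group), R)
    chol = np.linalg.cholesky(R * np.outer(draw_sd, draw_sd))

    X = draw_mean + rng.standard_normal((n, len(draw_mean))) @ chol.T
    total_draws, rejected = n, 0
    bad = (X <= 0).any(axis=1)
    while bad.any():
        k = int(bad.sum())
        rejected += k
        total_draws += k
        if total_draws >= 1000 and rejected / total_draws > 0.5:
            raise ConfigurationError(
                "rejection rate above 50% over "
                f"{total_draws} draws: degenerate amino-acid marginals")
        X[bad] = draw_mean + rng.standard_normal((k, len(draw_mean))) @ chol.T
        bad = (X <= 0).any(axis=1)

    if demographics is None:
        demo = (config.demographics_case if group == "case"
                else config.demographics_control)
    elif isinstance(demographics, DemographicMargins):
        demo = demographics
    elif demographics in ("case", "control"):
        demo = (config.demographics_case if demographics == "case"
                else config.demographics_control)
    else:
        raise ValueError(f"demographics must be None, 'case', 'control' or "
                         f"DemographicMargins, got {demographics!r}")
    if demo.age_uniform:
        age = rng.uniform(*demo.age_range, size=n)
    else:
        age = _sample_truncated_normal(rng, demo.age_mean, demo.age_sd,
                                       *demo.age_range, n)
    gender = _sample_categorical(rng, demo.gender, n)
    smoking = _sample_categorical(rng, demo.smoking, n)
    bmi = rng.normal(demo.bmi_mean, demo.bmi_sd, size=n)
    if group == "case":
        stage = _sample_categorical(rng, config.stage_margins, n)
        histology = _sample_categorical(rng, config.histology_margins, n)
    else:
        stage = np.full(n, "NA", dtype=object)
        histology = np.full(n, "NA", dtype=object)

    prefix = id_prefix if id_prefix is not None else f"{group}-s{seed}"
    df = pd.DataFrame({
        "subject_id": [f"{prefix}-{i:06d}" for i in range(n)],
        "group": group,
        "age": age,
        "gender": gender,
        "smoking": smoking,
        "bmi": bmi,
        "stage": stage,
        "histology": histology,
    })
    for j, a in enumerate(config.amino_acid_names):
        df[a] = X[:, j]
    return df
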