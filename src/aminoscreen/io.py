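"""Cohort CSV readers/writers with schema validation.

Fixed header: subject_id, group, age, gender, smoking, bmi, stage,
histology, then the 21 amino-acid columns in canonical order; UTF-8 with a
'.' decimal separator.  Unknown extra columns are preserved and passed
through.  Amino-acid column synonyms (full names, common abbreviations)
are rejected with a suggestion rather than silently accepted.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .synthetic_data import AMINO_ACIDS

__all__ = ["read_cohort", "write_cohort", "write_scores", "write_roc",
           "write_json", "COHORT_COLUMNS"]

COHORT_COLUMNS: tuple[str, ...] = (
    "subject_id", "group", "age", "gender", "smoking", "bmi", "stage",
    "histology", *AMINO_ACIDS)

#: lower-cased alternate spellings -> canonical three-letter code
SYNONYMS: dict[str, str] = {
    "threonine": "Thr", "serine": "Ser", "asparagine": "Asn",
    "glutamate": "Glu", "glutamic acid": "Glu", "glutamine": "Gln",
    "proline": "Pro", "glycine": "Gly", "alanine": "Ala",
    "citrulline": "Cit", "alpha-aminobutyric acid": "ABA",
    "2-aminobutyric acid": "ABA", "aaba": "ABA", "valine": "Val",
    "methionine": "Met", "isoleucine": "Ile", "leucine": "Leu",
    "tyrosine": "Tyr", "phenylalanine": "Phe", "histidine": "His",
    "tryptophan": "Trp", "ornithine": "Orn", "lysine": "Lys",
    "arginine": "Arg",
}


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`~aminoscreen.errors.SchemaError` (with row numbers
    where applicable) on missing or misnamed columns, duplicate subject
    ids, or non-numeric / non-positive concentrations.
    """
    # "NA" is a meaningful category (controls' stage/histology), not a
    # missing value
    df = pd.read_csv(path, dtype={"subject_id": str},
                     keep_default_na=False, na_values=[""],
                     float_precision="round_trip")
    lowered = {c.lower(): c for c in df.columns}
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        hints = []
        for col in missing:
            for syn, canonical in SYNONYMS.items():
                if canonical == col and syn in lowered:
                    hints.append(f"{lowered[syn]!r} should be the canonical "
                                 f"name {col!r}")
        detail = f" ({'; '.join(hints)})" if hints else ""
        raise SchemaError(f"{path}: missing column(s) {missing}{detail}")

    dup = df["subject_id"].duplicated(keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()     # 1-based incl. header
        raise SchemaError(f"{path}: duplicate subject_id at row(s) {rows}")

    bad_group = ~df["group"].isin(["case", "control"])
    if bad_group.any():
        rows = (df.index[bad_group] + 2).tolist()
        raise SchemaError(f"{path}: group must be 'case' or 'control' at "
                          f"row(s) {rows}")

    for a in AMINO_ACIDS:
        values = pd.to_numeric(df[a], errors="coerce")
        non_numeric = values.isna() & df[a].notna()
        if non_numeric.any() or df[a].isna().any():
            rows = (df.index[non_numeric | df[a].isna()] + 2).tolist()
            raise SchemaError(f"{path}: non-numeric or missing {a} "
                              f"concentration at row(s) {rows}")
        non_positive = values <= 0
        if non_positive.any():
            rows = (df.index[non_positive] + 2).tolist()
            raise SchemaError(f"{path}: non-positive {a} concentration at "
                              f"row(s) {rows}")
        df[a] = values
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort CSV in the fixed column order (extras appended)."""
    extras = [c for c in df.columns if c not in COHORT_COLUMNS]
    ordered = [c for c in COHORT_COLUMNS if c in df.columns] + extras
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, ordered].to_csv(path, index=False)


def write_scores(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


write_roc = write_scores


def write_json(obj, path) -> None:
    """Deterministic JSON (sorted keys, fixed separators)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
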