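"""Matched case-control construction.

Each case is paired with ``m`` controls that share its gender and smoking
category exactly and lie within an age caliper, chosen greedily by smallest
age difference without replacement.  The resulting strata are the
conditioning units for the downstream conditional logistic regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MatchingError

__all__ = ["MatchedSet", "match_controls", "matched_dataframe",
           "standardized_mean_difference"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchedSet:
    """One conditioning stratum: a case and its m matched controls."""

    stratum_id: int
    case_id: str
    control_ids: tuple[str, ...]


def _require_columns(df: pd.DataFrame, name: str) -> None:
    missing = [c for c in ("subject_id", "age", "gender", "smoking")
               if c not in df.columns]
    if missing:
        raise MatchingError(f"{name} table is missing columns {missing}")


def match_controls(cases: pd.DataFrame, pool: pd.DataFrame, ratio: int = 3,
                   caliper: float = 5.0, seed: int = 0,
                   allow_partial: bool = False) -> list[MatchedSet]:
    """Greedy 1:``ratio`` nearest-age matching without replacement.

    Cases are processed in an order randomised by ``seed``; for each case
    the unused pool controls with identical gender and smoking status and
    ``|age_control - age_case| <= caliper`` are ranked by age difference
    (ties broken by a seeded random draw) and the closest ``ratio`` are
    taken.  Subjects with missing gender or smoking are excluded with a
    logged warning.

    Raises :class:`~aminoscreen.errors.MatchingError` naming every case
    with fewer than ``ratio`` eligible unused controls, unless
    ``allow_partial`` is set, in which case those cases are dropped and
    logged.
    """
    if ratio < 1:
        raise ValueError(f"ratio must be >= 1, got {ratio}")
    if caliper < 0:
        raise ValueError(f"caliper must be >= 0, got {caliper}")
    _require_columns(cases, "cases")
    _require_columns(pool, "pool")
    overlap = set(cases["subject_id"]) & set(pool["subject_id"])
    if overlap:
        raise MatchingError(
            f"case and pool tables share subject ids: {sorted(overlap)[:5]}")

    def _complete(df: pd.DataFrame, name: str) -> pd.DataFrame:
        ok = df["gender"].notna() & df["smoking"].notna()
        ok &= (df["gender"] != "") & (df["smoking"] != "")
        if (~ok).any():
            logger.warning("excluding %d %s subject(s) with missing "
                           "gender/smoking from matching",
                           int((~ok).sum()), name)
        return df.loc[ok].reset_index(drop=True)

    cases = _complete(cases, "case")
    pool = _complete(pool, "pool")

    rng = np.random.default_rng(int(seed))
    order = rng.permutation(len(cases))

    pool_age = pool["age"].to_numpy(dtype=float)
    pool_cell = (pool["gender"].astype(str) + "|"
                 + pool["smoking"].astype(str)).to_numpy()
    pool_ids = pool["subject_id"].astype(str).to_numpy()
    used = np.zeros(len(pool), dtype=bool)

    strata: list[MatchedSet] = []
    failed: list[str] = []
    for stratum_id, idx in enumerate(order, start=1):
        case = cases.iloc[int(idx)]
        cell = f"{case['gender']}|{case['smoking']}"
        diffs = np.abs(pool_age - float(case["age"]))
        eligible = np.flatnonzero(~used & (pool_cell == cell)
                                  & (diffs <= caliper))
        tie_break = rng.random(eligible.size)
        if eligible.size < ratio:
            failed.append(str(case["subject_id"]))
            continue
        chosen = eligible[np.lexsort((tie_break, diffs[eligible]))][:ratio]
        used[chosen] = True
        strata.append(MatchedSet(
            stratum_id=stratum_id,
            case_id=str(case["subject_id"]),
            control_ids=tuple(pool_ids[chosen]),
        ))

    if failed:
        if not allow_partial:
            raise MatchingError(
                f"{len(failed)} case(s) have fewer than {ratio} eligible "
                f"unused controls within the ±{caliper} y caliper: "
                f"{failed}", failed_case_ids=failed)
        logger.warning("dropping %d unmatched case(s): %s",
                       len(failed), failed)

    # renumber strata 1..S in emission order for a stable output
    return [MatchedSet(i, s.case_id, s.control_ids)
            for i, s in enumerate(strata, start=1)]


def matched_dataframe(strata: list[MatchedSet], cases: pd.DataFrame,
                      pool: pd.DataFrame) -> pd.DataFrame:
    """Long-format matched table: case and control rows with a stratum_id.

    Within each stratum the case row comes first, then its controls in
    matched order.
    """
    cases_by_id = cases.set_index(cases["subject_id"].astype(str))
    pool_by_id = pool.set_index(pool["subject_id"].astype(str))
    rows = []
    for s in strata:
        case_row = cases_by_id.loc[s.case_id].copy()
        case_row["stratum_id"] = s.stratum_id
        rows.append(case_row)
        for cid in s.control_ids:
            ctrl_row = pool_by_id.loc[cid].copy()
            ctrl_row["stratum_id"] = s.stratum_id
            rows.append(ctrl_row)
    out = pd.DataFrame(rows).reset_index(drop=True)
    cols = ["stratum_id"] + [c for c in out.columns if c != "stratum_id"]
    return out[cols]


def standardized_mean_difference(x_case: np.ndarray,
                                 x_control: np.ndarray) -> float:
    """Cohen-style SMD: (mean difference) / pooled SD — a balance metric."""
    x_case = np.asarray(x_case, dtype=float)
    x_control = np.asarray(x_control, dtype=float)
    pooled = np.sqrt((x_case.var(ddof=1) + x_control.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((x_case.mean() - x_control.mean()) / pooled)
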