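"""Shared fixtures: a study-scale matched data set built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from aminoscreen import (
    generate_cohort,
    load_default_params,
    match_controls,
    matched_dataframe,
)
from aminoscreen.synthetic_data import matching_pool_margins

#: panel selected by the original screening analysis; used as the default
#: six-variable discriminant model throughout the tests
PANEL = ("Ala", "Val", "Ile", "His", "Trp", "Orn")


@pytest.fixture(scope="session")
def config():
    return load_default_params()


@pytest.fixture(scope="session")
def study_data(config):
    """141 cases, a 4000-control recruitment pool, and the 1:3 matched set."""
    cases = generate_cohort(config, "case", 141, seed=101)
    pool = generate_cohort(config, "control", 4000, seed=102,
                           demographics=matching_pool_margins(config))
    strata = match_controls(cases, pool, ratio=3, caliper=5.0, seed=103)
    matched = matched_dataframe(strata, cases, pool)
    return {"cases": cases, "pool": pool, "strata": strata,
            "matched": matched}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
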