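from __future__ import annotations

import logging

import pandas as pd
import pytest

from dmclaims import ScenarioConfig, simulate_scenario
from dmclaims.pipeline import detect_and_classify

logging.getLogger("dmclaims").setLevel(logging.ERROR)


def make_diagnoses(rows) -> pd.DataFrame:
    """rows: (person_id, icd3, setting, certainty, year, quarter)"""
    return pd.DataFrame(
        rows,
        columns=["person_id", "icd3", "setting", "certainty", "year", "quarter"],
    )


def make_prescriptions(rows) -> pd.DataFrame:
    """rows: (person_id, atc, year, quarter)"""
    return pd.DataFrame(rows, columns=["person_id", "atc", "year", "quarter"])


@pytest.fixture(scope="session")
def noiseless_run():
    """Noiseless regime: every onset yields a detectable, correctly coded
    record set; used for exact round-trip and recovery checks."""
    config = ScenarioConfig.noiseless(
        n_persons=30_000, years=(2019, 2020), rng_seed=11
    )
    data = simulate_scenario(config)
    risk_sets, cases = detect_and_classify(data, [2019, 2020])
    return config, data, risk_sets, cases


@pytest.fixture(scope="session")
def noisy_run():
    """Default (noisy) scenario at small scale, two reporting years."""
    config = ScenarioConfig(n_persons=20_000, years=(2019, 2020), rng_seed=7)
    data = simulate_scenario(config)
    risk_sets, cases = detect_and_classify(data, [2019, 2020])
    return config, data, risk_sets, cases
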