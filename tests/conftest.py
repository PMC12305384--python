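import numpy as np
import pandas as pd
import pytest

from opioidpgx import load_scenario, run_scenario


@pytest.fixture(scope="session")
def headline_small():
    """One shared headline run (n=8000) reused by cohort/pipeline tests."""
    data, result, report = run_scenario(
        "headline", seed=20260925, analysis="A", n_persons=8000
    )
    return data, result, report


@pytest.fixture(scope="session")
def headline_config():
    return load_scenario("headline")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def make_demographics(rows):
    """rows: list of (person_id, age, sex, race, mme)."""
    return pd.DataFrame(
        rows, columns=["person_id", "age", "sex", "race", "mme_per_day"]
    )


def make_episodes(rows):
    """rows: (person_id, drug, drug_class, strength, start_day, end_day)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "person_id", "drug", "drug_class", "inhibitor_strength",
            "start_day", "end_day",
        ],
    )
    epoch = pd.Timestamp("2018-01-01")
    df["start_date"] = epoch + pd.to_timedelta(df.pop("start_day"), unit="D")
    df["end_date"] = epoch + pd.to_timedelta(df.pop("end_day"), unit="D")
    df["source_count"] = 1
    return df


def make_encounters(rows):
    """rows: (person_id, day, setting, code)."""
    df = pd.DataFrame(rows, columns=["person_id", "day", "setting", "code"])
    df["date"] = pd.Timestamp("2018-01-01") + pd.to_timedelta(df.pop("day"), unit="D")
    return df


def make_phenotypes(rows):
    """rows: (person_id, diplotype, score, phenotype)."""
    return pd.DataFrame(
        rows,
        columns=["person_id", "diplotype", "genotype_activity_score", "phenotype"],
    )


def empty_rx():
    return pd.DataFrame(
        {
            "person_id": pd.Series(dtype=int),
            "drug": pd.Series(dtype=str),
            "drug_class": pd.Series(dtype=str),
            "inhibitor_strength": pd.Series(dtype=str),
            "start_date": pd.Series(dtype="datetime64[ns]"),
            "quantity": pd.Series(dtype=int),
        }
    )
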