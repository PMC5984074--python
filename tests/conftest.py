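"""Shared fixtures: small deterministic pedigrees and synthetic colonies."""

import numpy as np
import pandas as pd
import pytest

from pedigrowth.pedigree import Pedigree, kinship_matrix
from pedigrowth.simulate import SimConfig, simulate_pedigree


@pytest.fixture(scope="session")
def trio_records():
    return [
        {"id": "kid", "sire": "dad", "dam": "mom", "sex": "F",
         "birth_date": "2005-06-01"},
        {"id": "dad", "sire": "0", "dam": "", "sex": "M", "birth_date": "2000-01-01"},
        {"id": "mom", "sire": "", "dam": "0", "sex": "F", "birth_date": "2000-01-01"},
    ]


@pytest.fixture(scope="session")
def fullsib_mating_ped():
    """Founder pair -> two full sibs -> their offspring (inbred)."""
    return Pedigree.from_records([
        {"id": "f1", "sire": "0", "dam": "0", "sex": "M"},
        {"id": "f2", "sire": "0", "dam": "0", "sex": "F"},
        {"id": "s1", "sire": "f1", "dam": "f2", "sex": "M"},
        {"id": "s2", "sire": "f1", "dam": "f2", "sex": "F"},
        {"id": "kid", "sire": "s1", "dam": "s2", "sex": "F"},
    ])


@pytest.fixture(scope="session")
def tiny_colony():
    """Small colony pedigree (~250 members) used widely in unit tests."""
    cfg = SimConfig(seed=7, carrying_capacity=60, n_founder_females=10,
                    n_founder_males=4, chrom_lengths=(100.0, 100.0))
    ped = simulate_pedigree(cfg)
    return cfg, ped


@pytest.fixture(scope="session")
def tiny_colony_kinship(tiny_colony):
    _, ped = tiny_colony
    return kinship_matrix(ped)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_measurements(rows):
    """Helper for hand-written measurement frames."""
    df = pd.DataFrame(rows)
    for col in ("bw", "crl", "wc"):
        if col not in df:
            df[col] = np.nan
    if "pregnant" not in df:
        df["pregnant"] = False
    df["pregnant"] = df["pregnant"].map(lambda v: bool(v) if pd.notna(v) else False)
    if "date" not in df:
        df["date"] = pd.to_datetime("2010-01-01") + pd.to_timedelta(
            (df["age"] * 365.25).round(), unit="D")
        df["date"] = df["date"].dt.date.astype(str)
    return df
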