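"""Shared fixtures: small pedigrees and a default synthetic population."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

from wildqg.pedigree import Pedigree, pedigree_from_frame, read_pedigree
from wildqg.simulate import SimulationConfig, simulate_population


def make_pedigree(csv_text: str) -> Pedigree:
    return read_pedigree(io.StringIO(csv_text))


@pytest.fixture
def trio() -> Pedigree:
    return make_pedigree("id,dam,sire,cohort,sex\nA,,,1,F\nB,,,1,M\nC,A,B,5,F\n")


@pytest.fixture
def full_sib_family() -> Pedigree:
    """Two founders, two full sibs, one full-sib-mating offspring."""
    return make_pedigree(
        "id,dam,sire,cohort,sex\n"
        "A,,,1,F\nB,,,1,M\nS1,A,B,2,F\nS2,A,B,2,M\nX,S1,S2,3,F\n"
    )


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int | None = None,
                    p_missing: float = 0.1) -> Pedigree:
    """Random valid pedigree: individual i draws parents among 0..i-1."""
    n_founders = n_founders or max(2, n // 5)
    rows = []
    for i in range(n):
        if i < n_founders:
            rows.append((f"i{i}", "", "", i // 10, "F" if i % 2 else "M"))
        else:
            dam = f"i{rng.integers(0, i)}" if rng.random() > p_missing else ""
            sire = f"i{rng.integers(0, i)}" if rng.random() > p_missing else ""
            if dam and dam == sire:
                sire = ""
            rows.append((f"i{i}", dam, sire, i // 10, "F" if i % 2 else "M"))
    df = pd.DataFrame(rows, columns=["id", "dam", "sire", "cohort", "sex"])
    return pedigree_from_frame(df)


@pytest.fixture(scope="session")
def default_population():
    """One default synthetic population, reused across tests."""
    return simulate_population(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def default_females(default_population):
    pheno = default_population.phenotypes
    return pheno[pheno["sex"] == "F"].reset_index(drop=True)
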