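import numpy as np
import pytest

from famlipid.heritability import BlockEigh
from famlipid.pedigree import (
    IndividualRecord,
    Pedigree,
    kinship_matrix,
    relationship_matrix,
)
from famlipid.simulate import SimulationConfig, simulate_pedigree


def ped_from_rows(rows):
    """rows: (family, id, father, mother, sex) with None for missing."""
    return Pedigree([IndividualRecord(*r) for r in rows])


@pytest.fixture
def trio():
    return ped_from_rows(
        [
            ("F1", "P", None, None, "male"),
            ("F1", "M", None, None, "female"),
            ("F1", "C", "P", "M", "female"),
        ]
    )


@pytest.fixture
def nuclear():
    """Father, mother, 2 sons, 1 daughter."""
    return ped_from_rows(
        [
            ("F1", "dad", None, None, "male"),
            ("F1", "mom", None, None, "female"),
            ("F1", "s1", "dad", "mom", "male"),
            ("F1", "s2", "dad", "mom", "male"),
            ("F1", "d1", "dad", "mom", "female"),
        ]
    )


@pytest.fixture
def cousin_marriage():
    """Grandparents -> two sibs -> first cousins who marry; inbred child."""
    return ped_from_rows(
        [
            ("F1", "gf", None, None, "male"),
            ("F1", "gm", None, None, "female"),
            ("F1", "u1", "gf", "gm", "male"),
            ("F1", "u2", "gf", "gm", "female"),
            ("F1", "w1", None, None, "female"),
            ("F1", "h2", None, None, "male"),
            ("F1", "c1", "u1", "w1", "male"),
            ("F1", "c2", "h2", "u2", "female"),
            ("F1", "kid", "c1", "c2", "male"),
        ]
    )


@pytest.fixture(scope="session")
def cohort300():
    """300 nuclear families with sibships 2-4, shared across tests."""
    cfg = SimulationConfig(n_families=300, sibship=(2, 4), seed=42)
    ped = simulate_pedigree(cfg, seed=42)
    A = relationship_matrix(kinship_matrix(ped))
    return ped, A, BlockEigh(A)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
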