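import pandas as pd
import pytest

import overuse_index as oi


@pytest.fixture(scope="session")
def small_structure():
    """5 systems x 2 hospitals, default truth, modest cell sizes."""
    return oi.generate_structure(
        n_systems=5, hospitals_per_system=("fixed", 2), seed=1, eligible_mean=8.0
    )


@pytest.fixture(scope="session")
def small_bundle(small_structure):
    """Materialized claims bundle for the small structure."""
    return oi.generate_cells_and_claims(small_structure, seed=3)


@pytest.fixture(scope="session")
def small_cells(small_structure):
    """Direct cell table (no claims) for the small structure."""
    cells, _ = oi.generate_cells(small_structure, seed=2)
    return cells


@pytest.fixture(scope="session")
def default_defs():
    return oi.default_indicator_definitions()


@pytest.fixture
def toy_beneficiaries():
    return pd.DataFrame(
        {
            "beneficiary_id": ["A", "B", "C"],
            "birth_date": pd.to_datetime(["1946-03-01", "1936-06-15", "1950-01-01"]),
            "sex": ["F", "M", "F"],
            "chronic_condition_count": [5, 9, 2],
        }
    )
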