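import pandas as pd
import pytest

from ewsfusion.core_model import load_scoring_table
from ewsfusion.experiments import prepare_labelled
from ewsfusion.synthetic_data import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def table():
    return load_scoring_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-admission default-mode cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_admissions=300, seed=7))


@pytest.fixture(scope="session")
def small_labelled(small_cohort, table) -> pd.DataFrame:
    return prepare_labelled(small_cohort, table)
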