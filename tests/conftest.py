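import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from osdsurvey import SyntheticConfig, generate_respondents, \
    score_respondents  # noqa: E402


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_respondents=600, seed=11)


@pytest.fixture(scope="session")
def small_records(small_config):
    records, truth = generate_respondents(small_config)
    return records, truth


@pytest.fixture(scope="session")
def small_scored(small_records):
    records, _ = small_records
    return score_respondents(records)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
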