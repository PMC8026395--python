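from pathlib import Path

import pytest

from lynchrrs import read_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def example_csv() -> Path:
    return DATA_DIR / "example_cohort.csv"


@pytest.fixture
def example_cohort(example_csv):
    return read_cohort(example_csv)
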