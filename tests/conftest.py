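from pathlib import Path

import pytest

from gaitsim.io import read_pointsets
from gaitsim.pipeline import similarity_tables
from gaitsim.simulate import GaitSimConfig, generate_cohort

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def disjoint_a():
    """Shipped fixture: first worked-example partition (diamond, circle)."""
    diamond, circle = read_pointsets(DATA_DIR / "disjoint_example_a.csv")
    return diamond, circle


@pytest.fixture(scope="session")
def disjoint_b():
    """Shipped fixture: second worked-example partition (diamond, circle)."""
    diamond, circle = read_pointsets(DATA_DIR / "disjoint_example_b.csv")
    return diamond, circle


@pytest.fixture(scope="session")
def default_config():
    return GaitSimConfig(seed=42)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def default_tables(default_cohort):
    return similarity_tables(default_cohort, mode="fuzzy")


@pytest.fixture(scope="session")
def small_config():
    """Cheap cohort for tests that only need structure, not statistics."""
    return GaitSimConfig(n_subjects=3, duration_s=4.0, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)
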