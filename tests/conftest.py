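import numpy as np
import pandas as pd
import pytest

from otukit.core_io import AnalysisConfig, CountTable, SampleMetadata, TaxonomyTable
from otukit.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cfg():
    return AnalysisConfig(rng_seed=42)


@pytest.fixture
def tiny_table():
    return CountTable(
        ("otu1", "otu2", "otu3"),
        ("sampleA", "sampleB"),
        np.array([[1, 2], [0, 5], [3, 0]]),
    )


def random_table(rng, n_otus=20, n_samples=10, max_count=100, prefix=""):
    return CountTable(
        tuple(f"{prefix}otu{i}" for i in range(n_otus)),
        tuple(f"{prefix}s{j}" for j in range(n_samples)),
        rng.integers(0, max_count, size=(n_otus, n_samples)),
    )


def make_metadata(rows):
    """Build a SampleMetadata from a list of (partial) row dicts."""
    defaults = {
        "subject_id": "subj",
        "mother_subject_id": None,
        "age_days": None,
        "age_bin": "",
        "sample_type": "child_stool",
        "domain": "bacteria_16S",
        "batch": "stool",
    }
    return SampleMetadata(pd.DataFrame([{**defaults, **r} for r in rows]))


@pytest.fixture(scope="session")
def default_study():
    """One default-preset study shared across read-only tests."""
    return simulate_study(SimulationConfig(seed=11))
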