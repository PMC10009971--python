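import numpy as np
import pandas as pd
import pytest

from ctfrag.simulate import CohortData, SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_variants() -> pd.DataFrame:
    """Three well-formed plasma variant calls."""
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s1", "s2"],
            "compartment": ["plasma", "plasma", "plasma"],
            "chrom": ["chr1", "chr2", "chr1"],
            "pos": [100, 200, 100],
            "ref": ["A", "C", "A"],
            "alt": ["T", "G", "T"],
            "ad": [5, 10, 0],
            "dp": [100, 50, 80],
            "vaf": [0.05, 0.2, 0.0],
        }
    )


@pytest.fixture
def tiny_fragments() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1"] * 6,
            "variant_key": ["chr1:100:A:T"] * 6,
            "length": [90, 120, 150, 166, 250, 300],
            "allele": ["ALT", "ALT", "ALT", "REF", "REF", "REF"],
        }
    )


@pytest.fixture(scope="session")
def small_cohort() -> CohortData:
    """A small but complete synthetic study shared across tests."""
    cfg = SimulationConfig(
        n_cancer_discovery=8,
        n_healthy_discovery=8,
        n_cancer_validation=6,
        n_healthy_validation=6,
        n_wbc_samples=16,
        wbc_sites_per_sample=120,
        mutations_per_sample=40.0,
        rng_seed=7,
    )
    return simulate_cohort(cfg)
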