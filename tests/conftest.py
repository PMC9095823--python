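import numpy as np
import pandas as pd
import pytest

from tmtdep import PeptideIntensityMatrix, SimConfig, simulate_dataset


@pytest.fixture
def tiny_matrix():
    """3 peptides x 9 samples (4 Wt, 5 Hom), fully observed."""
    rng = np.random.default_rng(42)
    samples = [f"Wt{i}" for i in range(1, 5)] + [f"Hom{i}" for i in range(1, 6)]
    frame = pd.DataFrame(
        rng.uniform(1e4, 1e6, size=(3, 9)),
        index=["pepA", "pepB", "pepC"],
        columns=samples,
    )
    groups = pd.Series(["Wt"] * 4 + ["Hom"] * 5, index=samples)
    return PeptideIntensityMatrix(frame, groups)


@pytest.fixture(scope="session")
def sim_dataset():
    """A mid-size simulated experiment with planted regulation, reused
    read-only across tests."""
    cfg = SimConfig(
        n_proteins=300,
        peptides_per_protein=(3, 8),
        frac_regulated=0.2,
        log2fc_magnitude=(1.0, 0.3),
        noise_cv=0.1,
        frac_shared_peptides=0.05,
        missing_rate=0.05,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dataset (no shared peptides, no missingness)."""
    cfg = SimConfig(
        n_proteins=60,
        peptides_per_protein=(2, 5),
        frac_regulated=0.3,
        noise_cv=0.0,
        frac_shared_peptides=0.0,
        missing_rate=0.0,
        seed=5,
    )
    return simulate_dataset(cfg)
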