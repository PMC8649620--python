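import numpy as np
import pandas as pd
import pytest

from pairedprog.synthetic_data import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest paired cohort with planted effects, shared across tests."""
    cfg = SimulationConfig(
        n_patients=20,
        n_genes=300,
        n_cancer_genes=40,
        n_up=10,
        n_down=10,
        n_subsets=2,
        subset_program_size=15,
        seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def toy_expression():
    """Four samples, three genes, easy arithmetic."""
    return pd.DataFrame(
        {
            "s1": [1.0, 4.0, 0.0],
            "s2": [3.0, 3.0, 0.0],
            "s3": [2.0, 5.0, 1.0],
            "s4": [2.0, 5.0, 1.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )


@pytest.fixture()
def toy_pairing():
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p2"],
            "initial_sample_id": ["s1", "s3"],
            "recurrent_sample_id": ["s2", "s4"],
            "tumor_status": ["recurrence", "progressive"],
            "histology": ["glioma", "glioma"],
        }
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
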