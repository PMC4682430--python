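import numpy as np
import pandas as pd
import pytest

from boltchip.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def design_sheet() -> pd.DataFrame:
    genotypes = ["R1", "R2", "R3", "S1", "S2", "S3"]
    return pd.DataFrame(
        {
            "sample_id": genotypes,
            "genotype_id": genotypes,
            "condition": [g[0] for g in genotypes],
        }
    )


@pytest.fixture
def small_config() -> SimulationConfig:
    """Desk-scale panel: few probes, proportionally fewer planted effects."""
    return SimulationConfig(
        seed=7,
        n_expr_probes=400,
        n_meth_probes=800,
        n_planted_degs=30,
        n_deg_up_in_s=14,
        n_deg_up_in_r=16,
        n_planted_dmrs=20,
        n_dems=6,
        mito_length=30_000,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
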