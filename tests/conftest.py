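import numpy as np
import pandas as pd
import pytest

from tissuespec.expression import ExpressionMatrix, counts_to_tpm
from tissuespec.simulate import SyntheticConfig, generate_expression


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """Reduced-scale synthetic design used by the generic unit tests."""
    return SyntheticConfig(
        n_genes=600,
        n_planted_psg=15,
        n_planted_asg=15,
        n_planted_stage=8,
        n_deg_up=10,
        n_deg_down=30,
        n_shared_deg_psg=5,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return generate_expression(small_config)


@pytest.fixture(scope="session")
def small_tpm(small_sim) -> ExpressionMatrix:
    return counts_to_tpm(small_sim.counts, small_sim.lengths)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def tpm_matrix():
    """Small hand-made TPM matrix builder (columns need not sum to 1e6)."""

    def build(data: dict, genes=None) -> ExpressionMatrix:
        df = pd.DataFrame(data, index=genes, dtype=float)
        df.index = df.index.astype(str)
        return ExpressionMatrix(df, "TPM", strict_tpm=False)

    return build
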