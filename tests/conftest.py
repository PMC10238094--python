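import numpy as np
import pytest

from scegrn import SyntheticConfig, generate_truth, simulate_multiome
from scegrn.links import GBMParams


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Desk-scale study: 3 cell types, 3 topics, 30 genes, 60 regions."""
    kw = dict(
        n_cell_types=3, cells_per_type=(40, 40, 20), n_topics=3,
        n_genes=30, n_tfs=3, n_regions=60, n_decoy_motifs=20,
        n_repressor_tfs=1, genome_length=1_500_000, tss_min_gap=25_000,
        targets_per_tf=4, seed=seed,
    )
    kw.update(overrides)
    return SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_truth():
    return generate_truth(small_config(seed=11))


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    return simulate_multiome(small_truth, small_config(seed=11))


@pytest.fixture(scope="session")
def fast_gbm():
    """Lighter ensemble for unit tests (defaults are exercised end to end)."""
    return GBMParams(n_estimators=100, learning_rate=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
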