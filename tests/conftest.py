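import numpy as np
import pytest

from etg3d import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def toy_cfg():
    """A reduced study: 2 chromosomes, 120 enhancers, 3 Hi-C datasets."""
    return synthetic.SimConfig(
        seed=7, n_enh=120, n_prom=20, k=20, n_datasets=3, chrom_len_bp=5_000_000
    )


@pytest.fixture(scope="session")
def toy_genome(toy_cfg):
    cat, prom, genes, true_pairs = synthetic.make_genome(toy_cfg)
    return {"cat": cat, "prom": prom, "genes": genes, "true_pairs": true_pairs}


@pytest.fixture(scope="session")
def toy_tads(toy_cfg):
    return synthetic.make_tad_hierarchy(toy_cfg)
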