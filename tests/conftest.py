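import numpy as np
import pytest

from emtnet import ConsensusSoftCluster, preprocess, synthdata


@pytest.fixture(scope="session")
def small_dataset():
    """Default synthetic dataset: 4 clusters, 200 cells, planted signaling."""
    return synthdata.generate_emt_dataset(synthdata.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free variant: no dropout, Poisson counts, silent background."""
    cfg = synthdata.SynthConfig(
        seed=5, dropout_rate=0.0, dispersion=0.0, mean_low=0.0, tc_fraction=0.1
    )
    return synthdata.generate_emt_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_model(small_dataset):
    """Consensus soft clustering fit on the default dataset (log1p values)."""
    filt = preprocess.filter_cells(small_dataset.expression, 0.05)
    sel = preprocess.select_genes(filt)
    log_expr = filt.subset_genes(sel.gene_ids).log1p()
    model = ConsensusSoftCluster(random_state=11).fit(log_expr.values)
    return filt, model


@pytest.fixture
def rng():
    return np.random.default_rng(123)
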