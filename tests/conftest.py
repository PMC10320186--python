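import numpy as np
import pytest

from mutstab.fixtures import make_labelled_dataset, make_peptide
from mutstab.model import SiameseDDGRegressor
from mutstab.pharmacophores import load_typing_table
from mutstab.signatures import SignatureConfig


@pytest.fixture(scope="session")
def typing():
    return load_typing_table()


@pytest.fixture(scope="session")
def helix():
    return make_peptide(10)


@pytest.fixture(scope="session")
def sig_cfg():
    return SignatureConfig()


@pytest.fixture(scope="session")
def linear_dataset():
    """Synthetic linear-label dataset at the study scale (n=2000, noise 0.1)."""
    return make_labelled_dataset(2000, seed=7, noise_sd=0.1)


@pytest.fixture(scope="session")
def trained_linear_model(linear_dataset):
    """A compact siamese model fitted on the first 1600 records of the
    synthetic dataset; shared across recovery/importance tests because
    training dominates the suite's runtime."""
    ds = linear_dataset
    X, y = ds.stacked(), ds.y
    est = SiameseDDGRegressor(
        sig_channels=ds.n_sig_channels, n_bins=ds.n_bins,
        conv_channels=(16, 32), transformer_dim=32, attention_heads=4,
        dense_units_comp=(64, 32), dense_units_head=32,
        dropout=0.0, learning_rate=3e-3, epochs=60, patience=10, seed=0,
    )
    n_train = 1600
    est.fit(X[:n_train], y[:n_train])
    return est, ds, n_train
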