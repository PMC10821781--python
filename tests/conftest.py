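import numpy as np
import pytest

from dcsflow import (AcquisitionSpec, HeadModel, TissueLayer, make_tau_grid,
                     baseline_head)


@pytest.fixture(scope="session")
def grid():
    return make_tau_grid()


@pytest.fixture(scope="session")
def head():
    return baseline_head()


@pytest.fixture(scope="session")
def acq30():
    return AcquisitionSpec(rho=30.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240117)


def homogeneous_head(mua, musp, Db):
    """Three-layer stack whose layers are all the same tissue."""
    return HeadModel([
        TissueLayer(mua=mua, musp=musp, Db=Db, thickness=5.0),
        TissueLayer(mua=mua, musp=musp, Db=Db, thickness=7.0),
        TissueLayer(mua=mua, musp=musp, Db=Db, thickness=50.0),
    ])


@pytest.fixture(scope="session")
def trained_network():
    """One desk-scale reference training run shared by the test session.

    Corpus and epoch budget are scaled down from the full recipe (the full
    corpus is exercised by scripts/acceptance.py); hyperparameters (Adam,
    lr 1e-5, batch 128, early stopping) are the reference ones.
    """
    from dcsflow.dataset import sample_params, synthesize_batch
    from dcsflow.net import DCSNet, TrainingConfig, train_model

    rng = np.random.default_rng(7)
    n = 60_000
    params = sample_params(rng, n)
    conds = rng.integers(0, 4, n)
    xs, ys = [], []
    for i in range(0, n, 20_000):
        x, y = synthesize_batch(params[i:i + 20_000], conds[i:i + 20_000],
                                rng)
        xs.append(x)
        ys.append(y)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n_tr = int(0.8 * n)
    net = DCSNet(seed=0)
    cfg = TrainingConfig(max_epochs=90, patience=20, seed=0)
    hist = train_model(net, x[:n_tr], y[:n_tr], x[n_tr:], y[n_tr:], cfg)
    return net, hist
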