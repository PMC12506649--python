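import numpy as np
import pytest

from ordselect import McmcSettings, OrdinalRidgeModel


def simulate_ordinal(n=300, k=50, gamma=(-0.5, 0.5), beta_sd=0.15, seed=0):
    """Self-simulated data from the threshold model (ground truth known)."""
    rng = np.random.default_rng(seed)
    X = rng.binomial(2, 0.5, (n, k)).astype(float)
    beta = rng.normal(0.0, beta_sd, k)
    eta = (X - X.mean(axis=0)) @ beta
    liab = eta + rng.standard_normal(n)
    y = np.searchsorted(np.asarray(gamma), liab) + 1
    return {"X": X, "y": y, "beta": beta, "eta": eta, "gamma": np.asarray(gamma)}


@pytest.fixture(scope="session")
def recovery_data():
    return simulate_ordinal(n=300, k=50, seed=11)


@pytest.fixture(scope="session")
def recovery_fit(recovery_data):
    d = recovery_data
    model = OrdinalRidgeModel(d["y"], d["X"])
    return model.fit(McmcSettings(6000, 2000, 4, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pmf(rng, C):
    v = rng.dirichlet(np.ones(C))
    return v / v.sum()
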