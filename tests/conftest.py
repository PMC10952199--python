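import numpy as np
import pytest
from scipy.special import expit

from confsel import dgm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20221031)


@pytest.fixture(scope="session")
def logistic_data():
    """A well-behaved simulated logistic dataset (no separation, n = 400)."""
    r = np.random.default_rng(7)
    n = 400
    L = r.standard_normal((n, 3))
    A = (r.random(n) < expit(0.4 * L[:, 0])).astype(float)
    eta = -0.5 + 0.6 * A + 0.8 * L[:, 0] + 0.3 * L[:, 1]
    Y = (r.random(n) < expit(eta)).astype(float)
    X = np.column_stack([np.ones(n), A, L])
    return X, Y


@pytest.fixture(scope="session")
def exp1_scenario():
    """A calibrated Experiment-1 scenario with real confounding."""
    sc = dgm.ScenarioExp1(
        scenario_id=9000, beta_la=0.4, beta_ly=0.4, n=120, event_fraction=0.5
    )
    return dgm.calibrated(sc, n_mc=300_000)


@pytest.fixture(scope="session")
def exp2_scenario():
    """A calibrated Experiment-2 scenario (n = 250, confounded, theta = log 1.5)."""
    all2 = dgm.enumerate_scenarios_exp2()
    # pick a theta=log(1.5), n=250 scenario whose mixture holds instruments+noise
    for sc in all2:
        if (
            sc.theta > 0
            and sc.n == 250
            and sc.role_counts()["instrument-class"] >= 3
            and sc.role_counts()["noise"] >= 3
        ):
            return dgm.calibrated(sc, n_mc=300_000)
    raise RuntimeError("fixture scenario not found")


@pytest.fixture(scope="session")
def small_dataset(exp2_scenario):
    return dgm.generate_dataset(exp2_scenario, seed=11)
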