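import numpy as np
import pytest

from drsm.simulate import SimulationCondition, simulate_dataset
from drsm.tree import ItemParameters, PersonParameters, four_point_tree, five_point_tree


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230206)


def random_person(rng, N=7, D=1, eta=True, kappa=False):
    return PersonParameters(
        theta=rng.standard_normal((N, D)),
        eta=rng.standard_normal(N) if eta else None,
        kappa=rng.standard_normal(N) if kappa else None,
    )


def random_item(rng, I=5, H=2, kappa=False):
    loadings = {
        "agree_trait": rng.uniform(0.1, 1.5, I),
        "extreme_trait": rng.uniform(0.0, 1.5, I),
        "extreme_ers": rng.uniform(0.0, 1.5, I),
    }
    if kappa:
        loadings["moderate_mrs"] = rng.uniform(0.0, 1.5, I)
    return ItemParameters(beta=rng.standard_normal((H, I)), loadings=loadings)


@pytest.fixture(scope="session")
def tree4():
    return four_point_tree()


@pytest.fixture(scope="session")
def tree5():
    return five_point_tree()


@pytest.fixture(scope="session")
def drsm_small_dataset():
    """One small DRSM-generated data set reused across estimator tests."""
    cond = SimulationCondition(
        variant="drsm", N=250, I=12,
        trait_trajectory=(0.8, 0.2), ers_trajectory=(0.3, 0.7),
        lam=2.0, base_seed=97,
    )
    return simulate_dataset(cond, 0)


@pytest.fixture(scope="session")
def drsm_fit(drsm_small_dataset):
    """One posterior fit of the dynamic model, shared across test modules."""
    from drsm.estimators import DRSM

    est = DRSM(chains=4, warmup=250, draws=250, random_state=11)
    est.fit(drsm_small_dataset.data)
    return est
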