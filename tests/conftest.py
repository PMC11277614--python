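import numpy as np
import pytest

import gmltmd as g

# canonical point estimates of the generalized model on the analogy test
ETA_TRUE = {(0, 0): 0.29, (0, 1): 0.77, (0, 2): 0.39, (1, 3): 0.87, (1, 4): -0.79}


@pytest.fixture(scope="session")
def analogy_q():
    return g.analogy_q_matrix()


@pytest.fixture(scope="session")
def analogy_cs(analogy_q):
    return g.analogy_component_structure(analogy_q)


@pytest.fixture(scope="session")
def analogy_partition(analogy_q, analogy_cs):
    return g.discrimination_partition(analogy_q, analogy_cs)


@pytest.fixture(scope="session")
def analogy_truth(analogy_q, analogy_cs):
    return g.analogy_true_parameters(analogy_q, analogy_cs, n_persons=100,
                                     rng=np.random.default_rng(12345))


@pytest.fixture(scope="session")
def small_structure():
    """3 items × 3 features, two components, every pattern distinct."""
    q = g.validate_feature_matrix(
        [[1, 1, 0], [0, 1, 1], [1, 0, 1]],
        item_ids=["i1", "i2", "i3"],
        feature_ids=["f1", "f2", "f3"],
    )
    cs = g.derive_component_matrix(q, [[1, 0], [1, 0], [0, 1]],
                                   component_ids=["g", "l"])
    return q, cs


@pytest.fixture(scope="session")
def tiny_fit():
    """One small fitted model, shared across tests that only need a FitResult."""
    q, cs, params, y = g.study_fixture(seed=99, n_persons=60)
    return g.fit_model(
        y, q, cs, "gmltmd",
        cfg=g.SamplerConfig(chains=2, warmup=200, samples=200, seed=7),
    ), y
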