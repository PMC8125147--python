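import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import logicoop as lc


@pytest.fixture(scope="session")
def toy():
    return lc.toy_model()


@pytest.fixture(scope="session")
def toy_s1(toy):
    return lc.set_inputs(toy, {"S": 1})


@pytest.fixture(scope="session")
def mini_emt():
    return lc.mini_emt_model()


@pytest.fixture(scope="session")
def negfb():
    return lc.negative_feedback_model()


def small_random_models(n, start_seed=0, max_boolean_equivalent=10, **kw):
    """Deterministic batch of random models with configuration spaces of at
    most 2**max_boolean_equivalent states."""
    n_components = kw.pop("n_components", None)
    models = []
    seed = start_seed
    while len(models) < n:
        spec = lc.GeneratorSpec(n_components=n_components or 4 + seed % 5,
                                max_in_degree=2,
                                frac_multivalued=0.3,
                                n_inputs=1,
                                seed=seed)
        model = lc.random_model(spec)
        if model.n_configurations() <= 2 ** max_boolean_equivalent:
            models.append(model)
        seed += 1
    return models
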