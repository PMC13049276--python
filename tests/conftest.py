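"""Shared fixtures: schedules, phantom corpora, and toy trained models.

Training the toy codec and score network is done once per session under
the study conditions in :mod:`lapsmri.toy` and shared across sampler,
hot-start, and acceptance tests; everything is seeded so the suite is
fully deterministic.
"""

import numpy as np
import pytest

from lapsmri.toy import toy_corpus, train_toy_models


@pytest.fixture(scope="session")
def toy_models():
    return train_toy_models(seed=0)


@pytest.fixture(scope="session")
def schedule():
    from lapsmri.schedule import make_schedule
    return make_schedule(1000)


@pytest.fixture(scope="session")
def phantom_corpus():
    return toy_corpus(100, seed=0)[:110]


@pytest.fixture(scope="session")
def codec64(toy_models):
    return toy_models[0]


@pytest.fixture(scope="session")
def toy_model(toy_models):
    return toy_models[1]


@pytest.fixture(scope="session")
def ident():
    from lapsmri.codec import identity_codec
    return identity_codec()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
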