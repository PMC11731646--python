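import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_z() -> pd.DataFrame:
    """Symmetric 3-sample z-matrix with closed-form delta distances."""
    return pd.DataFrame(
        [[1.0, 2.0, 2.0], [2.0, 1.0, 2.0], [2.0, 2.0, 1.0]],
        index=["a", "b", "c"],
        columns=["f1", "f2", "f3"],
    )


@pytest.fixture
def center2_meta():
    from costylo.designs import center2_metadata

    return center2_metadata()


@pytest.fixture(scope="session")
def small_corpus():
    """A small mixed synthetic corpus shared across tests (lam=0.6)."""
    from costylo.synthetic import center2_config, generate_corpus

    cfg = center2_config(
        lam=0.6, words_per_pair=3000, vocab_size=1000, seed=11
    )
    return generate_corpus(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
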