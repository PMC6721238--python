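import numpy as np
import pytest

from healthineq.synthetic import default_config, generate_population


@pytest.fixture(scope="session")
def cfg_2005():
    return default_config("2005-like", n_respondents=5_000, seed=11)


@pytest.fixture(scope="session")
def survey_2005(cfg_2005):
    return generate_population(cfg_2005, include_latent=True)


@pytest.fixture(scope="session")
def two_wave_table():
    """A small two-wave survey table for pipeline integration tests."""
    import pandas as pd

    frames = []
    for profile, seed in (("2005-like", 21), ("2009-like", 22)):
        cfg = default_config(profile, n_respondents=1_500, seed=seed)
        frames.append(generate_population(cfg))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
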