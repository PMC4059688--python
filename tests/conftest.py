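import numpy as np
import pytest

from imfsieve import (
    FixtureSpec,
    MultichannelSeries,
    NoiseConfig,
    SiftConfig,
    memd,
    na_memd_decompose,
)
from imfsieve.memd import ROLE_DATA, ROLE_NOISE


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240616)


@pytest.fixture(scope="session")
def small_noise_dec():
    """All-noise composite decomposition reused by significance tests:
    2 'data' + 6 reference channels of white noise, 512 samples."""
    rng = np.random.default_rng(11)
    values = np.hstack([
        rng.normal(size=(512, 2)),
        np.sqrt(0.06) * rng.normal(size=(512, 6)),
    ])
    sig = MultichannelSeries(
        values, 1000.0,
        roles=[ROLE_DATA] * 2 + [ROLE_NOISE] * 6,
        labels=["d0", "d1"] + [f"n{i}" for i in range(6)],
    )
    return memd(sig, K=16)


@pytest.fixture(scope="session")
def small_fixture_dec():
    """A reduced trivariate-fixture NA-MEMD decomposition (0.75 s, K=16,
    6 reference channels) shared across tests that only need a realistic
    decomposition, not the full-size benchmark problem."""
    spec = FixtureSpec(duration_s=0.75, seed=5)
    return na_memd_decompose(
        __import__("imfsieve").make_fixture(spec),
        NoiseConfig(m=6, seed=6), K=16,
    )
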