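import numpy as np
import pytest

import bodycues as bc
from bodycues import experiments as ex


@pytest.fixture(scope="session")
def skeleton():
    return bc.default_skeleton()


@pytest.fixture(scope="session")
def strong_corpus():
    """Small corpus with a strong lie-movement effect (shared across tests)."""
    cfg = bc.SyntheticConfig(
        n_interviewees=6, session_length_s=30.0, lie_movement_multiplier=2.5, seed=11
    )
    return bc.generate_corpus(cfg)


@pytest.fixture(scope="session")
def strong_features(strong_corpus):
    return ex.extract_corpus(strong_corpus)


@pytest.fixture(scope="session")
def strong_dataset(strong_features):
    return strong_features.dataset("session")


@pytest.fixture(scope="session")
def one_session():
    cfg = bc.SyntheticConfig(n_interviewees=2, session_length_s=30.0, seed=5)
    return bc.generate_session(cfg, "truth", "game", "p0", seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    """A uniformly random proper rotation matrix (QR-based)."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
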